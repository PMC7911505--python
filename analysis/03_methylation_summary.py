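"""Summarize average and per-CpG methylation by tissue and group.

Reads the cohort frames written by 02_run_pipeline.py and reports the
headline methylation contrasts: the tissue difference among untreated
fish and the treatment shift per tissue, for both amplicons, plus the
most- and least-methylated CpG sites.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"
OUT = ROOT / "results" / "methylation_summary.tsv"


def main():
    rows = []
    for amp in ("Tph1A_like", "BDNF_like"):
        frame = pd.read_csv(RUN / "tables" / f"{amp}_cohort_frame.tsv",
                            sep="\t")
        g = frame.groupby(["tissue", "group"])["mean_meth"]
        print(f"\n{amp}: average methylation (%, mean +/- SE over fish)")
        for (tissue, group), sub in g:
            se = sub.std(ddof=1) / len(sub) ** 0.5
            print(f"  {tissue:5s} {group:6s} {sub.mean():6.2f} +/- {se:.2f}")
            rows.append({"amplicon": amp, "tissue": tissue, "group": group,
                         "mean_pct": sub.mean(), "se_pct": se, "n": len(sub)})
        cpg_cols = [c for c in frame.columns if c.startswith("cpg_")]
        ctrl = frame[frame.group == "CTRL"]
        site_means = ctrl[cpg_cols].mean().sort_values()
        print(f"  untreated per-CpG range: {site_means.iloc[0]:.2f}% at "
              f"{site_means.index[0][4:]} .. {site_means.iloc[-1]:.2f}% at "
              f"{site_means.index[-1][4:]}")
        mean_stats = pd.concat(
            pd.read_csv(RUN / "stats" / f"{amp}_{t}_mean.tsv", sep="\t")
            .assign(tissue=t) for t in ("brain", "gut"))
        for _, r in mean_stats.iterrows():
            print(f"  CTRL vs PROBIO mean, {r.tissue}: t = {r.statistic:.2f},"
                  f" p = {r.p_raw:.3g}")
    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
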