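"""Epiallele-class comparisons and 5hmC estimate.

Reports which epiallele classes shift between CTRL and PROBIO per tissue
(raw p primary, Holm-Sidak adjusted alongside, as is conventional for
class-distribution comparisons), and the BS-minus-oxBS 5hmC level.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"


def main():
    for tissue in ("brain", "gut"):
        df = pd.read_csv(RUN / "stats" / f"Tph1A_like_{tissue}_per_class.tsv",
                         sep="\t")
        hits = df[(~df.absent) & (df.p_raw < 0.05)]
        print(f"\n{tissue}: classes shifted at raw p < 0.05 "
              f"(of {int((~df.absent).sum())} present)")
        if hits.empty:
            print("  none")
        for _, r in hits.iterrows():
            k = r.feature.split("_")[1]
            direction = "down in PROBIO" if r.statistic > 0 else "up in PROBIO"
            print(f"  {k}-Meth: t = {r.statistic:+.2f}, p = {r.p_raw:.4f} "
                  f"(adj {r.p_adj:.3f}) -> {direction}")

    hmc = pd.read_csv(RUN / "tables" / "Tph1A_like_hmc.tsv", sep="\t")
    print(f"\n5hmC (BS - oxBS), all samples x CpGs: "
          f"mean {hmc.hmc_pct.mean():.2f}%, "
          f"raw difference mean {hmc.raw_diff_pct.mean():.2f}%, "
          f"max {hmc.hmc_pct.max():.2f}%")
    per_group = hmc.assign(group=hmc["sample"].str.split("_").str[1]) \
        .groupby("group").hmc_pct.mean()
    print("by group:", ", ".join(f"{g} {v:.2f}%" for g, v in per_group.items()))


if __name__ == "__main__":
    main()
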