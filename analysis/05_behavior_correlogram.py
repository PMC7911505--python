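"""Methylation-behavior correlogram.

Pools CTRL and PROBIO within each tissue and reports the Pearson
correlations between methylation features (average, per-CpG, epiallele
classes) and the behavior scores DV, OA and CP, highlighting significant
cells; writes a heatmap per tissue.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"
FIG = ROOT / "results" / "figures"


def main():
    FIG.mkdir(parents=True, exist_ok=True)
    for tissue in ("brain", "gut"):
        df = pd.read_csv(
            RUN / "stats" / f"Tph1A_like_{tissue}_correlogram.tsv", sep="\t")
        sig = df[df.p < 0.05].sort_values("p")
        print(f"\n{tissue}: significant feature-score correlations (p < 0.05)")
        for _, r in sig.iterrows():
            print(f"  {r.feature:10s} ~ {r.score}: r = {r.r:+.2f}, "
                  f"p = {r.p:.4f} {r.sig}")
        mat = df.pivot(index="feature", columns="score", values="r")
        order = (["mean_meth"]
                 + sorted([f for f in mat.index if f.startswith("cpg_")],
                          key=lambda s: int(s[4:]))
                 + sorted([f for f in mat.index if f.startswith("class_")],
                          key=lambda s: int(s.split("_")[1])))
        mat = mat.loc[order, ["DV", "OA", "CP"]]
        fig, ax = plt.subplots(figsize=(4, 8))
        sns.heatmap(mat, cmap="RdBu_r", vmin=-1, vmax=1, ax=ax,
                    cbar_kws={"label": "Pearson r"})
        ax.set_title(f"Tph1A-like, {tissue}")
        fig.tight_layout()
        path = FIG / f"correlogram_{tissue}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        print(f"  heatmap -> {path}")


if __name__ == "__main__":
    main()
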