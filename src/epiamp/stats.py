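"""Group comparisons and methylation-behavior correlation.

The comparisons follow the study design conventions of small-cohort
amplicon work: two-sided pooled-variance t-tests between groups, Holm-
Sidak step-down adjustment across the CpGs of an amplicon, per-class
tests reported raw (with the adjusted value alongside), and Pearson
correlation between methylation features and behavioral scores pooled
across treatment groups within a tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SCORES = ("DV", "OA", "CP")


@dataclass(frozen=True)
class TestResult:
    feature: str
    statistic: float
    p_raw: float
    p_adj: float | None
    adjust_method: str | None
    n_x: int
    n_y: int


def two_group_ttest(x, y, feature: str = "") -> TestResult:
    """Two-sided unpaired t-test assuming equal variances (pooled SD).

    t = (mean_x - mean_y) / (s_p * sqrt(1/n_x + 1/n_y)) with the pooled
    variance s_p^2 on n_x + n_y - 2 degrees of freedom. Degenerate input
    with zero variance in both groups and equal means returns t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    dx = x.mean() - y.mean()
    ssq = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df = nx + ny - 2
    sp2 = ssq / df
    if sp2 == 0.0:
        if dx == 0.0:
            return TestResult(feature, 0.0, 1.0, None, None, nx, ny)
        t = np.inf if dx > 0 else -np.inf
    else:
        t = dx / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(feature, float(t), float(min(p, 1.0)), None, None, nx, ny)


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Sort ascending; the i-th order statistic (1-based) over m tests becomes
    1 - (1 - p_(i))^(m - i + 1); enforce monotone non-decreasing down the
    sorted list; return in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _attach_adjusted(results: list[TestResult], method: str) -> list[TestResult]:
    adj = holm_sidak([r.p_raw for r in results])
    return [
        TestResult(r.feature, r.statistic, r.p_raw, float(a), method, r.n_x, r.n_y)
        for r, a in zip(results, adj)
    ]


def _group_split(cohort: pd.DataFrame, tissue: str, columns: list[str]):
    sub = cohort[cohort["tissue"] == tissue]
    g1 = sub[sub["group"] == "CTRL"]
    g2 = sub[sub["group"] == "PROBIO"]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(f"need >=2 samples per group in tissue {tissue!r}")
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort frame lacks columns: {missing}")
    return g1, g2


def per_cpg_comparison(cohort: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """CTRL vs PROBIO t-test per CpG column, Holm-Sidak over the amplicon."""
    cols = [c for c in cohort.columns if c.startswith("cpg_")]
    if not cols:
        raise ValueError("cohort frame has no cpg_* columns")
    g1, g2 = _group_split(cohort, tissue, cols)
    results = [two_group_ttest(g1[c], g2[c], feature=c) for c in cols]
    results = _attach_adjusted(results, "holm-sidak")
    return pd.DataFrame([r.__dict__ for r in results])


def per_class_comparison(cohort: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """CTRL vs PROBIO t-test per epiallele class.

    Per convention for class-distribution comparisons the raw p is the
    primary readout; the Holm-Sidak adjusted value is reported alongside.
    Classes absent in every sample of the tissue are flagged and excluded
    from the adjustment family.
    """
    cols = [c for c in cohort.columns if c.startswith("class_")]
    if not cols:
        raise ValueError("cohort frame has no class_* columns")
    g1, g2 = _group_split(cohort, tissue, cols)
    present, absent = [], []
    for c in cols:
        if (g1[c].sum() + g2[c].sum()) > 0:
            present.append(c)
        else:
            absent.append(c)
    results = [two_group_ttest(g1[c], g2[c], feature=c) for c in present]
    results = _attach_adjusted(results, "holm-sidak")
    df = pd.DataFrame([r.__dict__ for r in results])
    df["absent"] = False
    for c in absent:
        df.loc[len(df)] = {"feature": c, "statistic": np.nan, "p_raw": np.nan,
                           "p_adj": np.nan, "adjust_method": None,
                           "n_x": len(g1), "n_y": len(g2), "absent": True}
    return df


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    return "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def behavior_correlogram(cohort: pd.DataFrame, tissue: str,
                         scores=SCORES) -> pd.DataFrame:
    """Pearson correlation of methylation features with behavioral scores.

    CTRL and PROBIO are pooled within the tissue (the treatment spans the
    biological range the correlation exploits). Features are the mean
    methylation, every per-CpG level and every class frequency. Returns a
    tidy frame of r, two-sided p (t-distribution, n-2 df) and significance
    stars; zero-variance features yield missing r.
    """
    sub = cohort[cohort["tissue"] == tissue]
    features = (["mean_meth"]
                + [c for c in cohort.columns if c.startswith("cpg_")]
                + [c for c in cohort.columns if c.startswith("class_")])
    rows = []
    for feat in features:
        for score in scores:
            pairs = sub[[feat, score]].dropna()
            f, s = pairs[feat].to_numpy(), pairs[score].to_numpy()
            if len(f) < 3 or np.std(f) == 0 or np.std(s) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(f, s)
            rows.append({"tissue": tissue, "feature": feat, "score": score,
                         "r": r, "p": p, "n": len(f), "sig": _stars(p)})
    return pd.DataFrame(rows)


def correlogram_matrix(correlogram: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy correlogram to a features x scores matrix of r."""
    return correlogram.pivot(index="feature", columns="score", values="r")
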