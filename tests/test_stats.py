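"""Group statistics: pooled t-test, Holm-Sidak, per-feature comparisons,
behavior correlogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from epiamp.stats import (behavior_correlogram, correlogram_matrix, holm_sidak,
                          per_class_comparison, per_cpg_comparison,
                          two_group_ttest)


def test_ttest_identical_groups():
    r = two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0 and r.p_raw == 1.0


def test_ttest_textbook_example():
    # pooled-variance t for {1,2,3} vs {4,5,6}
    r = two_group_ttest([1, 2, 3], [4, 5, 6])
    assert r.statistic == pytest.approx(-3.674, abs=1e-3)
    assert r.p_raw == pytest.approx(0.0214, abs=1e-3)


def test_ttest_sign_flips_with_group_swap(rng):
    x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
    a, b = two_group_ttest(x, y), two_group_ttest(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_raw == pytest.approx(b.p_raw)


def test_ttest_degenerate_and_errors():
    assert two_group_ttest([2, 2], [2, 2]).p_raw == 1.0
    r = two_group_ttest([2, 2], [3, 3])        # zero variance, unequal means
    assert r.p_raw == pytest.approx(0.0)
    with pytest.raises(ValueError):
        two_group_ttest([1], [2, 3])


def test_ttest_cross_oracle_scipy(rng):
    for _ in range(20):
        x = rng.normal(0, 2, rng.integers(2, 12))
        y = rng.normal(0.5, 2, rng.integers(2, 12))
        r = two_group_ttest(x, y)
        t, p = sps.ttest_ind(x, y, equal_var=True)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_raw == pytest.approx(p, abs=1e-10)


def test_holm_sidak_frozen_example():
    got = holm_sidak([0.01, 0.03, 0.04])
    assert got == pytest.approx([0.029701, 0.0591, 0.0591], abs=1e-4)


def test_holm_sidak_edges():
    assert holm_sidak([0.2]) == pytest.approx([0.2])
    assert (holm_sidak([1.0, 1.0, 1.0]) == 1.0).all()
    with pytest.raises(ValueError):
        holm_sidak([0.5, 1.5])


@settings(derandomize=True, max_examples=150)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
def test_holm_sidak_properties(pvals):
    adj = holm_sidak(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1.0).all()
    # order statistics of adjusted follow order of raw
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_holm_sidak_cross_oracle_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.uniform(0, 1, 15)
    ours = holm_sidak(p)
    theirs = multipletests(p, method="holm-sidak")[1]
    assert ours == pytest.approx(theirs, abs=1e-12)


def _cohort(rng, n_cpg=3, n_classes=4, shift=0.0):
    rows = []
    for tissue in ("brain", "gut"):
        for group in ("CTRL", "PROBIO"):
            for i in range(5):
                row = {"sample_id": f"{tissue}{group}{i}", "tissue": tissue,
                       "group": group, "chemistry": "BS",
                       "DV": rng.normal(), "OA": rng.normal(),
                       "CP": rng.normal(), "mean_meth": rng.normal(50, 5)}
                for j in range(n_cpg):
                    mu = 50 + (shift if group == "PROBIO" and j == 0 else 0)
                    row[f"cpg_{j}"] = rng.normal(mu, 3)
                for k in range(n_classes):
                    row[f"class_{k}"] = rng.uniform(0, 1)
                row["class_absent"] = 0.0
                rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def test_per_cpg_comparison_matches_bruteforce_loop(rng):
    cohort = _cohort(rng, shift=10.0)
    out = per_cpg_comparison(cohort, "brain")
    sub = cohort[cohort.tissue == "brain"]
    raw = []
    for c in ["cpg_0", "cpg_1", "cpg_2"]:
        raw.append(two_group_ttest(sub[sub.group == "CTRL"][c],
                                   sub[sub.group == "PROBIO"][c]).p_raw)
    assert list(out.p_raw) == pytest.approx(raw, abs=1e-12)
    assert list(out.p_adj) == pytest.approx(list(holm_sidak(raw)), abs=1e-12)
    assert (out.p_adj >= out.p_raw - 1e-12).all()


def test_per_cpg_single_site_adjustment_is_identity(rng):
    cohort = _cohort(rng, n_cpg=3)
    keep = [c for c in cohort.columns if not c.startswith("cpg_")] + ["cpg_0"]
    out = per_cpg_comparison(cohort[keep], "gut")
    assert len(out) == 1
    assert out.p_adj.iloc[0] == pytest.approx(out.p_raw.iloc[0], abs=1e-12)


def test_per_class_comparison_flags_absent_classes(rng):
    cohort = _cohort(rng)
    out = per_class_comparison(cohort, "gut")
    absent = out[out.feature == "class_absent"]
    assert bool(absent.absent.iloc[0])
    assert absent.p_raw.isna().all()
    present = out[~out.absent]
    assert present.p_raw.notna().all()
    # raw p primary, adjusted reported alongside
    assert {"p_raw", "p_adj"} <= set(out.columns)


def test_null_false_positive_rate(rng):
    """Raw per-class t-tests under the null flag ~5% at p<0.05."""
    n_rep, n_classes = 200, 8
    flags = total = 0
    for _ in range(n_rep):
        x = rng.dirichlet(np.ones(n_classes) * 5, size=5)
        y = rng.dirichlet(np.ones(n_classes) * 5, size=5)
        for k in range(n_classes):
            total += 1
            flags += two_group_ttest(x[:, k], y[:, k]).p_raw < 0.05
    rate = flags / total
    se = np.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) < 4 * se


def test_correlogram_perfect_and_invariances(rng):
    cohort = _cohort(rng)
    cohort.loc[cohort.tissue == "gut", "DV"] = \
        2 * cohort.loc[cohort.tissue == "gut", "mean_meth"] + 1
    out = behavior_correlogram(cohort, "gut")
    row = out[(out.feature == "mean_meth") & (out.score == "DV")].iloc[0]
    assert row.r == pytest.approx(1.0)
    assert row.p < 1e-8 and row.sig == "**"
    # affine rescaling leaves r untouched
    cohort2 = cohort.copy()
    cohort2["DV"] = -3 * cohort2["DV"] + 7
    out2 = behavior_correlogram(cohort2, "gut")
    row2 = out2[(out2.feature == "mean_meth") & (out2.score == "DV")].iloc[0]
    assert row2.r == pytest.approx(-1.0)


def test_correlogram_zero_variance_missing(rng):
    cohort = _cohort(rng)
    cohort["class_0"] = 0.25
    out = behavior_correlogram(cohort, "brain")
    assert out[(out.feature == "class_0")].r.isna().all()
    mat = correlogram_matrix(out)
    assert set(mat.columns) == {"DV", "OA", "CP"}


def test_correlogram_null_r_near_zero(rng):
    rows = []
    n = 400
    for i in range(n):
        rows.append({"sample_id": f"s{i}", "tissue": "gut", "group": "CTRL",
                     "chemistry": "BS", "DV": rng.normal(), "OA": rng.normal(),
                     "CP": rng.normal(), "mean_meth": rng.normal(50, 5),
                     "class_0": rng.uniform()})
    out = behavior_correlogram(pd.DataFrame(rows).set_index("sample_id",
                                                            drop=False), "gut")
    r = out[(out.feature == "mean_meth") & (out.score == "DV")].r.iloc[0]
    assert abs(r) < 3 / np.sqrt(n)
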