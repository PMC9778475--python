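"""Wilcoxon rank-sum DE, BH adjustment, fold changes and summaries,
each checked against an independent oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import screg as sg

from conftest import make_nm


def exact_rank_sum_p(x, y):
    """Two-sided p by exhaustive enumeration of all group assignments,
    measuring extremeness as distance of the rank sum from its mean."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    mu = n1 * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for c in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(c)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def _two_group_nm(x, y):
    nm = make_nm(np.concatenate([x, y])[None, :])
    groups = pd.Series(["A"] * len(x) + ["B"] * len(y), index=nm.barcodes)
    return nm, groups


def test_wilcoxon_fully_tied_gene_gives_p_one():
    nm, groups = _two_group_nm([1.0] * 4, [1.0] * 4)
    assert sg.wilcoxon_de(nm, groups).iloc[0] == 1.0


def test_wilcoxon_canonical_example_normal_vs_exact():
    """{1,2,3} vs {4,5,6}: normal approximation 0.0809, exact 0.100."""
    nm, groups = _two_group_nm([1.0, 2, 3], [4.0, 5, 6])
    p = sg.wilcoxon_de(nm, groups).iloc[0]
    assert p == pytest.approx(0.0809, abs=2e-4)
    assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.100, abs=1e-12)
    assert abs(p - 0.100) <= 0.03


@pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 4), (5, 6), (6, 6)])
def test_wilcoxon_close_to_exact_enumeration_continuous(n1, n2):
    """Without ties, the normal approximation tracks exact enumeration
    within 0.03 in the tail (exact p <= 0.2) and 0.04 everywhere."""
    rng = np.random.default_rng(n1 * 10 + n2)
    for _ in range(20):
        x = rng.normal(size=n1)
        y = rng.normal(loc=rng.uniform(-2, 2), size=n2)
        nm, groups = _two_group_nm(x, y)
        p = sg.wilcoxon_de(nm, groups).iloc[0]
        exact = exact_rank_sum_p(x, y)
        assert abs(p - exact) <= (0.03 if exact <= 0.2 else 0.04)


@pytest.mark.parametrize("n1,n2", [(5, 6), (6, 6)])
def test_wilcoxon_close_to_exact_enumeration_zero_inflated(n1, n2):
    """With half the values tied at zero (single-cell dropout), the
    tie-corrected approximation still holds the tail within 0.03; the
    chunky mid-range of the discrete null can deviate more."""
    rng = np.random.default_rng(n1 * 100 + n2)
    for _ in range(20):
        x = rng.normal(size=n1)
        y = rng.normal(loc=rng.uniform(-2, 2), size=n2)
        x[: n1 // 2] = 0.0
        y[: n2 // 2] = 0.0
        nm, groups = _two_group_nm(x, y)
        p = sg.wilcoxon_de(nm, groups).iloc[0]
        exact = exact_rank_sum_p(x, y)
        assert abs(p - exact) <= (0.03 if exact <= 0.2 else 0.07)


def test_wilcoxon_matches_scipy_mannwhitneyu_per_gene():
    rng = np.random.default_rng(2)
    X = rng.poisson(2.0, size=(40, 30)).astype(float)
    nm = make_nm(X)
    groups = pd.Series(["A"] * 14 + ["B"] * 16, index=nm.barcodes)
    ours = sg.wilcoxon_de(nm, groups)
    for gi in range(40):
        x, y = X[gi, :14], X[gi, 14:]
        if np.ptp(X[gi]) == 0:
            expected = 1.0
        else:
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        assert ours.iloc[gi] == pytest.approx(expected, abs=1e-10)


def test_wilcoxon_invariant_to_cell_order():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 12))
    nm = make_nm(X)
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=nm.barcodes)
    perm = rng.permutation(12)
    nm2 = make_nm(X[:, perm], barcodes=[f"c{i}" for i in perm])
    np.testing.assert_allclose(
        sg.wilcoxon_de(nm, groups).to_numpy(),
        sg.wilcoxon_de(nm2, groups.iloc[perm]).to_numpy(),
    )


def test_wilcoxon_needs_three_cells_per_group():
    nm, groups = _two_group_nm([1.0, 2], [3.0, 4, 5])
    with pytest.raises(ValueError, match="3 cells"):
        sg.wilcoxon_de(nm, groups)


def bh_brute_force(p):
    """Literal step-up: q(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    for pos, idx in enumerate(order):
        q = min(p[order[j]] * n / (j + 1) for j in range(pos, n))
        out[idx] = min(q, 1.0)
    return out


def test_bh_hand_examples():
    np.testing.assert_allclose(sg.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(sg.bh_adjust([0.001, 0.5]), [0.002, 0.5])
    np.testing.assert_allclose(sg.bh_adjust([0.2]), [0.2])


def test_bh_matches_brute_force_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    for _ in range(25):
        p = rng.uniform(size=rng.integers(1, 40))
        ours = sg.bh_adjust(p)
        np.testing.assert_allclose(ours, bh_brute_force(p), rtol=1e-12)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        sg.bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        sg.bh_adjust([-0.1])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
def test_bh_dominates_raw_p_and_stays_in_unit_interval(p):
    adj = sg.bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all((adj >= 0) & (adj <= 1))


def test_log2fc_on_delogged_means():
    # treated de-logged mean 3, control 1, pseudocount 1 -> log2(4/2) = 1
    ctrl = np.log1p(np.array([1.0, 1.0]))
    trt = np.log1p(np.array([3.0, 3.0]))
    nm = make_nm(np.concatenate([ctrl, trt])[None, :])
    groups = pd.Series(["ctr", "ctr", "pnb", "pnb"], index=nm.barcodes)
    lfc = sg.log2_fold_change(nm, groups, treated="pnb", control="ctr")
    assert lfc.iloc[0] == pytest.approx(1.0)
    # identical groups -> 0; swapping labels negates
    assert sg.log2_fold_change(nm, groups, "ctr", "pnb").iloc[0] == pytest.approx(-1.0)


def test_signed_significance():
    assert sg.signed_significance([0.01], [-2.0])[0] == pytest.approx(-2.0)
    assert sg.signed_significance([1.0], [3.0])[0] == 0.0
    assert sg.signed_significance([0.01], [0.0])[0] == 0.0
    # p-floor keeps the score finite
    assert np.isfinite(sg.signed_significance([0.0], [1.0])[0])


def _fake_signature(n_up, n_down, n_other):
    lfc = np.concatenate([np.full(n_up, 2.0), np.full(n_down, -2.0), np.zeros(n_other)])
    padj = np.concatenate([np.full(n_up + n_down, 1e-5), np.full(n_other, 0.5)])
    return pd.DataFrame(
        {"log2fc": lfc, "pval": padj, "padj": padj,
         "signed_score": sg.signed_significance(padj, lfc)},
        index=[f"g{i}" for i in range(n_up + n_down + n_other)],
    )


def test_de_summary_counts_and_fraction():
    sig = _fake_signature(3, 2, 5)
    out = sg.de_summary(sig, padj_max=0.01, lfc_min=1.0)
    assert (out["n_up"], out["n_down"], out["n_total"]) == (3, 2, 5)
    assert out["fraction_of_detected"] == pytest.approx(50.0)


def test_de_summary_empty_signature():
    out = sg.de_summary(_fake_signature(0, 0, 0))
    assert out == {"n_up": 0, "n_down": 0, "n_total": 0, "fraction_of_detected": 0.0}


def test_de_summary_strict_lfc_threshold():
    sig = _fake_signature(1, 0, 0)
    sig.loc["g0", "log2fc"] = 1.0  # exactly 1 is not "> 1"
    assert sg.de_summary(sig)["n_up"] == 0


def test_null_dataset_is_calibrated(null_run):
    """No planted effects: raw p roughly uniform, nothing at FDR 0.05
    for >=95% of genes."""
    sig = null_run.sig
    assert (sig["padj"] > 0.05).mean() >= 0.95
    ks = stats.kstest(sig["pval"], "uniform")
    assert ks.pvalue > 0.01
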