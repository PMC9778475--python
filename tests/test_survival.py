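"""Kaplan-Meier, Cox/Wald, Fisher integration and evidence ranking."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import screg as sg
from screg.survival import km_by_group, nes_to_onesided_p, wald_to_onesided_p


def km_oracle(time, event):
    """Hand product-limit: multiply (1 - d/n) over distinct event times."""
    out = {}
    s = 1.0
    for t in sorted(set(t for t, e in zip(time, event) if e)):
        n = sum(1 for ti in time if ti >= t)
        d = sum(1 for ti, ei in zip(time, event) if ti == t and ei)
        s *= 1 - d / n
        out[t] = s
    return out


def test_km_four_distinct_events():
    km = sg.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose(km["survival"], [1.0, 0.75, 0.5, 0.25, 0.0])
    assert km["time"].iloc[0] == 0.0  # S(0) = 1


def test_km_all_censored_is_flat():
    km = sg.km_estimate([1, 2, 3], [0, 0, 0])
    np.testing.assert_allclose(km["survival"], [1.0])


def test_km_late_censoring_leaves_steps_unchanged():
    base = sg.km_estimate([1, 2], [1, 1])
    with_tail = sg.km_estimate([1, 2, 10], [1, 1, 0])
    # earlier steps change because the risk set grows; the late censored
    # subject adds no step of its own
    assert len(with_tail) == len(base)
    km = sg.km_estimate([1, 2, 3], [1, 1, 0])
    assert km["time"].tolist() == [0.0, 1.0, 2.0]


def test_km_exhaustive_four_subject_censoring_patterns():
    """All 16 event/censor patterns on 4 subjects match the hand
    product-limit oracle, including tied times."""
    for times in ([1, 2, 3, 4], [1, 1, 2, 3]):
        for pattern in product([0, 1], repeat=4):
            km = sg.km_estimate(times, list(pattern))
            oracle = km_oracle(times, list(pattern))
            steps = dict(zip(km["time"][1:], km["survival"][1:]))
            assert steps.keys() == oracle.keys()
            for t in oracle:
                assert steps[t] == pytest.approx(oracle[t])
            assert (km["survival"].diff().dropna() <= 1e-12).all()  # non-increasing


def test_km_rejects_nonpositive_time():
    with pytest.raises(ValueError):
        sg.km_estimate([0.0, 1.0], [1, 1])


def test_stratify_expression_quartiles():
    expr = pd.Series([3.0, 1.0, 7.0, 5.0, 2.0, 8.0, 6.0, 4.0])
    strata = sg.stratify_expression(expr, 4)
    assert strata.value_counts().tolist() == [2, 2, 2, 2]
    # monotone in expression: boundaries at order statistics 2|4|6
    ordered = strata[expr.sort_values().index]
    assert ordered.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]


def test_stratify_expression_errors():
    with pytest.raises(ValueError, match="constant"):
        sg.stratify_expression(pd.Series([1.0, 1.0, 1.0, 1.0]), 2)
    with pytest.raises(ValueError):
        sg.stratify_expression(pd.Series([1.0, 2.0]), 4)


def test_cox_null_two_identical_groups():
    time = [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6]
    event = [1] * 12
    expr = [0.0] * 6 + [1.0] * 6
    fit = sg.cox_wald(pd.DataFrame({"time": time, "event": event, "expr": expr}))
    assert abs(fit["beta"]) < 1e-6
    assert fit["pval"] > 0.99


def test_cox_recovers_true_hazard_ratio():
    cohort = sg.generate_survival_cohort(500, gene_hr=2.0, censor_rate=0.3, seed=11)
    fit = sg.cox_wald(cohort)
    assert abs(fit["beta"] - np.log(2)) <= 0.2
    assert abs(fit["score_residual"]) < 1e-8  # score equation solved
    assert fit["pval"] < 1e-6


def test_cox_null_hazard_ratio_within_two_se():
    cohort = sg.generate_survival_cohort(300, gene_hr=1.0, censor_rate=0.2, seed=5)
    fit = sg.cox_wald(cohort)
    assert abs(fit["beta"]) <= 2 * fit["se"]


def test_cox_covariate_rescaling_identity():
    cohort = sg.generate_survival_cohort(200, gene_hr=1.8, censor_rate=0.2, seed=3)
    fit = sg.cox_wald(cohort)
    scaled = cohort.copy()
    scaled["expr"] = scaled["expr"] * 5.0
    fit5 = sg.cox_wald(scaled)
    assert fit5["beta"] == pytest.approx(fit["beta"] / 5.0, rel=1e-6)
    assert fit5["wald_z"] == pytest.approx(fit["wald_z"], rel=1e-6)


def test_cox_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    cohort = sg.generate_survival_cohort(200, gene_hr=2.0, censor_rate=0.3, seed=7)
    fit = sg.cox_wald(cohort)
    cph = lifelines.CoxPHFitter()
    cph.fit(cohort[["time", "event", "expr"]], duration_col="time", event_col="event")
    assert fit["beta"] == pytest.approx(cph.params_["expr"], rel=1e-4)
    assert fit["se"] == pytest.approx(cph.standard_errors_["expr"], rel=1e-3)


def test_cox_error_paths():
    no_events = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "expr": [0.0, 1.0]})
    with pytest.raises(ValueError, match="events"):
        sg.cox_wald(no_events)
    constant = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "expr": [1.0] * 3})
    with pytest.raises(ValueError, match="constant"):
        sg.cox_wald(constant)


def test_degenerate_cohort_exercises_error_path():
    cohort = sg.generate_survival_cohort(10, gene_hr=1.5, censor_rate=0.99, seed=0)
    if cohort["event"].sum() < 2:
        with pytest.raises(ValueError):
            sg.cox_wald(cohort)


def test_fisher_closed_forms():
    x2, df, p = sg.fisher_integrate([0.5, 0.5])
    assert x2 == pytest.approx(2.7726, abs=1e-4)
    assert df == 4
    assert p == pytest.approx(0.5966, abs=1e-4)
    # k=1 identity: chi2_2 survival of -2 ln p is p itself
    for single in (0.01, 0.3, 0.9):
        assert sg.fisher_integrate([single])[2] == pytest.approx(single, rel=1e-12)
    assert sg.fisher_integrate([1.0, 1.0])[2] == pytest.approx(1.0)


def test_fisher_rejects_zero_and_empty():
    with pytest.raises(ValueError):
        sg.fisher_integrate([0.0, 0.5])
    with pytest.raises(ValueError):
        sg.fisher_integrate([])


def test_fisher_matches_scipy():
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.uniform(0.01, 1.0, size=rng.integers(1, 8))
        x2, df, combined = sg.fisher_integrate(p)
        ref = stats.combine_pvalues(p, method="fisher")
        assert x2 == pytest.approx(ref.statistic)
        assert combined == pytest.approx(ref.pvalue)


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8))
def test_fisher_permutation_invariant_and_monotone(p):
    x2, df, combined = sg.fisher_integrate(p)
    x2r, dfr, combined_r = sg.fisher_integrate(list(reversed(p)))
    assert combined == pytest.approx(combined_r)
    smaller = [pi * 0.5 for pi in p]
    assert sg.fisher_integrate(smaller)[2] <= combined + 1e-12


def test_integrate_evidence_ranking():
    tbl = pd.DataFrame(
        {"s1": [0.01, 0.5, 1.0], "s2": [0.02, 0.5, 1.0]},
        index=["tfA", "tfB", "tfC"],
    )
    ranked = sg.integrate_evidence(tbl)
    assert ranked.index[0] == "tfA"
    # chi2.sf(-2(ln .01 + ln .02), 4) = 0.0019
    assert ranked.loc["tfA", "integrated_p"] == pytest.approx(0.001903, abs=1e-5)
    assert ranked.loc["tfB", "integrated_p"] == pytest.approx(0.5966, abs=1e-4)
    assert ranked.loc["tfC", "integrated_p"] == pytest.approx(1.0)
    assert ranked.loc["tfC", "rank"] == 3


def test_integrate_evidence_missing_sources_shrink_df():
    tbl = pd.DataFrame(
        {"s1": [0.05, 0.05], "s2": [np.nan, 0.05]}, index=["partial", "full"]
    )
    ranked = sg.integrate_evidence(tbl)
    assert ranked.loc["partial", "df"] == 2
    assert ranked.loc["full", "df"] == 4
    assert ranked.loc["partial", "integrated_p"] == pytest.approx(0.05)


def test_one_sided_conversions_point_the_right_way():
    assert nes_to_onesided_p(-3.0) < 0.01  # strong repression: small p
    assert nes_to_onesided_p(3.0) > 0.99
    assert wald_to_onesided_p(3.0) < 0.01  # high expression, poor outcome
    assert wald_to_onesided_p(-3.0) > 0.99


def test_km_by_group_stratified_cohort():
    cohort = sg.generate_survival_cohort(80, gene_hr=3.0, censor_rate=0.2, seed=2)
    strata = sg.stratify_expression(cohort["expr"], 4)
    curves = km_by_group(cohort, strata)
    assert set(curves) == {0, 1, 2, 3}
    for km in curves.values():
        assert km["survival"].iloc[0] == 1.0
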