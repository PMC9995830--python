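"""Cohort statistics: transforms, D'Agostino skewness test, f² power
analysis, single-predictor models, sequential Bonferroni, contingency
test, group summaries, Likert summaries, and the full pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from woolsim import (
    arcsine_sqrt,
    bonferroni_sequential,
    chisq_independence,
    dagostino_skew_test,
    fit_single_predictor,
    generate_cohort,
    group_summary,
    likert_summary,
    run_study_pipeline,
    solve_f2,
)
from woolsim.study_stats import power_from_f2
from woolsim.synthetic_participants import EffectSpec

# ---------------------------------------------------------------- transform


@pytest.mark.parametrize(
    "pct, expected", [(0.0, 0.0), (100.0, math.pi / 2), (50.0, math.pi / 4)]
)
def test_arcsine_sqrt_anchor_points(pct, expected):
    assert arcsine_sqrt(pct) == pytest.approx(expected)


def test_arcsine_sqrt_domain_error():
    with pytest.raises(ValueError):
        arcsine_sqrt(101.0)


@settings(derandomize=True, max_examples=60)
@given(
    a=st.floats(0, 100, allow_nan=False),
    b=st.floats(0, 100, allow_nan=False),
)
def test_arcsine_sqrt_strictly_monotone(a, b):
    if a < b:
        assert arcsine_sqrt(a) < arcsine_sqrt(b)


# ------------------------------------------------------- D'Agostino skewness


def test_skew_test_symmetric_sample():
    sample = [-2, -1, 0, 1, 2] * 4
    res = dagostino_skew_test(sample)
    assert res.skewness == pytest.approx(0.0)
    assert res.z_stat == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [1, 7, 23])
def test_skew_test_z_matches_published_transformation(seed):
    """z agrees with a direct evaluation of the skewness standardization
    and Johnson SU transformation formulas."""
    x = np.random.default_rng(seed).gamma(2.0, size=63)
    res = dagostino_skew_test(x)
    n = x.size
    m2 = np.mean((x - x.mean()) ** 2)
    m3 = np.mean((x - x.mean()) ** 3)
    g1 = m3 / m2**1.5
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6 * (n - 2)))
    beta2 = 3 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1 + math.sqrt(2 * (beta2 - 1))
    delta = 1 / math.sqrt(math.log(math.sqrt(w2)))
    alpha = math.sqrt(2 / (w2 - 1))
    z = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1))
    assert res.skewness == pytest.approx(g1)
    assert res.z_stat == pytest.approx(z, rel=1e-10)
    assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-10)


@pytest.mark.parametrize("n", [5, 8, 50_000])
def test_skew_test_sample_size_contract(n):
    with pytest.raises(ValueError, match="sample size"):
        dagostino_skew_test(np.zeros(n) + np.arange(n))


def test_skew_test_type_one_error_rate():
    """Under normal data at n = 63 the test rejects ~5% of the time."""
    rng = np.random.default_rng(0)
    rejections = sum(
        dagostino_skew_test(rng.normal(size=63)).p_value < 0.05 for _ in range(1000)
    )
    assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------- f² power


def test_detectable_effect_size_for_study_design():
    assert round(solve_f2(u=1, v=61, alpha=0.05, power=0.95), 2) == 0.21


def test_f2_vanishes_as_power_approaches_alpha():
    assert solve_f2(1, 61, 0.05, 0.0501) < 1e-3


def test_f2_monotone_in_power_and_denominator_df():
    assert solve_f2(1, 61, 0.05, 0.99) > solve_f2(1, 61, 0.05, 0.80)
    assert solve_f2(1, 200, 0.05, 0.95) < solve_f2(1, 61, 0.05, 0.95)


def test_f2_root_reproduces_requested_power():
    f2 = solve_f2(1, 61, 0.05, 0.95)
    assert power_from_f2(f2, 1, 61, 0.05) == pytest.approx(0.95, abs=1e-8)


def test_f2_validated_by_regression_simulation():
    """Monte-Carlo power of the F test on simulated regressions with the
    solved effect size hits the requested power within ±0.01."""
    u, v, alpha, target = 1, 61, 0.05, 0.95
    n = v + 2
    f2 = solve_f2(u, v, alpha, target)
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 1, size=n)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    sigma = 1.0
    b1 = math.sqrt(f2 * (u + v + 1) * sigma**2 / sxx)  # ncp convention f2*(u+v+1)
    reps = 20_000
    eps = rng.normal(0, sigma, size=(reps, n))
    y = b1 * x + eps
    yc = y - y.mean(axis=1, keepdims=True)
    bhat = yc @ xc / sxx
    ssr = bhat**2 * sxx
    sse = (yc**2).sum(axis=1) - ssr
    fstat = ssr / (sse / (n - 2))
    crit = sps.f.isf(alpha, 1, n - 2)
    assert abs((fstat > crit).mean() - target) < 0.01


# ------------------------------------------------------ single-predictor OLS


def test_perfect_linear_relationship_saturates_fit():
    spec = EffectSpec(planted_f2=0.0, seed=5)
    table = generate_cohort(spec)
    table.df["recall"] = 2.0 * table.df["time_played"] + 1.0
    res = fit_single_predictor(table, "recall", "time_played", transform=False)
    assert res.r2_adj > 0.999999
    assert res.p_raw < 1e-12


def test_two_level_predictor_degrees_of_freedom():
    table = generate_cohort(EffectSpec(seed=3))
    res = fit_single_predictor(table, "recall", "farming_experience")
    assert res.df == (1, 61)


def test_multi_level_predictor_degrees_of_freedom():
    table = generate_cohort(EffectSpec(seed=3))
    res = fit_single_predictor(table, "recall", "moving_type")
    k = table.df["moving_type"].nunique()
    assert res.df == (k - 1, 63 - k)


def test_constant_predictor_is_degenerate():
    table = generate_cohort(EffectSpec(seed=3))
    table.df["control_problems"] = True
    with pytest.raises(ValueError, match="degenerate"):
        fit_single_predictor(table, "recall", "control_problems")


def test_missing_values_dropped_listwise():
    table = generate_cohort(EffectSpec(seed=3))
    table.df.loc[:4, "accuracy"] = np.nan
    res = fit_single_predictor(table, "accuracy", "time_played")
    assert res.n_dropped == 5
    assert res.df == (1, 63 - 5 - 2)


def test_null_predictor_type_one_error_rate():
    """With no planted effect the time-played model rejects ~5% of cohorts."""
    rejections = 0
    n_reps = 1000
    for s in range(n_reps):
        table = generate_cohort(EffectSpec(planted_f2=0.0, seed=20_000 + s))
        res = fit_single_predictor(table, "recall", "time_played")
        rejections += res.p_raw < 0.05
    assert abs(rejections / n_reps - 0.05) <= 0.015


def test_f_test_invariant_to_predictor_rescaling():
    table = generate_cohort(EffectSpec(planted_f2=0.21, seed=9))
    res1 = fit_single_predictor(table, "recall", "time_played")
    table.df["time_played"] = 3.5 * table.df["time_played"] - 11.0
    res2 = fit_single_predictor(table, "recall", "time_played")
    assert res1.p_raw == pytest.approx(res2.p_raw, rel=1e-9)
    assert res1.F == pytest.approx(res2.F, rel=1e-9)


# ------------------------------------------------------ sequential Bonferroni


@pytest.mark.parametrize(
    "raw, corrected",
    [
        ([0.03], [0.03]),
        ([0.03, 0.03, 0.03], [0.03, 0.06, 0.09]),
        ([0.6, 0.9], [0.6, 1.0]),
    ],
)
def test_sequential_bonferroni_multiplier_is_test_count(raw, corrected):
    assert bonferroni_sequential(raw) == pytest.approx(corrected)


def test_sequential_bonferroni_rejects_invalid_p():
    with pytest.raises(ValueError):
        bonferroni_sequential([0.5, 1.2])


# ------------------------------------------------------------- chi-squared


def test_nine_by_two_table_degrees_of_freedom(rng):
    table = rng.integers(1, 30, size=(9, 2))
    _, dof, _ = chisq_independence(table)
    assert dof == 8


def test_proportional_rows_give_exact_independence():
    stat, _, p = chisq_independence([[10, 20], [5, 10], [50, 100]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_two_by_two_statistic_matches_hand_computation():
    obs = np.array([[10.0, 20.0], [20.0, 10.0]])
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    by_hand = ((obs - expected) ** 2 / expected).sum()
    stat, dof, _ = chisq_independence(obs)
    assert dof == 1
    assert stat == pytest.approx(by_hand)


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        chisq_independence([[0, 0], [5, 10]])


# ----------------------------------------------------------- group summaries


def test_constant_group_not_flagged():
    g = group_summary([7.0] * 10, "const")
    assert g.lower_quartile == g.upper_quartile == g.mean
    assert g.ci95_low == g.ci95_high == g.mean
    assert not g.poor_estimate  # strict inequalities at the boundary


def test_large_normal_sample_is_flagged():
    """At n = 400 the CI of the mean (±~0.1) is far tighter than the
    quartiles (±~0.67), so the spread flag fires."""
    x = np.random.default_rng(0).normal(size=400)
    assert group_summary(x, "normal").poor_estimate


@pytest.mark.parametrize("seed", range(8))
def test_flag_matches_brute_force_rule(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=rng.integers(3, 40)) * rng.uniform(0.1, 10)
    g = group_summary(x, "mc")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    half = sps.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / math.sqrt(len(x))
    expected = (q1 < x.mean() - half) or (q3 > x.mean() + half)
    assert g.poor_estimate == expected


def test_group_summary_needs_two_values():
    with pytest.raises(ValueError):
        group_summary([1.0], "tiny")


# ------------------------------------------------------------------- Likert


def test_likert_percentages():
    counts = pd.DataFrame(
        {"negative": [0, 10, 3], "neutral": [0, 10, 7], "positive": [30, 10, 20]},
        index=["s1", "s2", "s3"],
    )
    pct = likert_summary(counts)
    assert pct.loc["s1"].tolist() == pytest.approx([0.0, 0.0, 100.0])
    assert pct.loc["s2"].tolist() == pytest.approx([100 / 3] * 3)
    assert pct.loc["s3"].tolist() == pytest.approx([10.0, 70 / 3, 200 / 3])
    assert (pct.sum(axis=1) - 100).abs().max() < 0.1


def test_likert_empty_row_skipped_with_warning():
    counts = pd.DataFrame(
        {"negative": [0, 1], "neutral": [0, 1], "positive": [0, 1]}, index=["a", "b"]
    )
    with pytest.warns(UserWarning, match="no responses"):
        pct = likert_summary(counts)
    assert list(pct.index) == ["b"]


# ----------------------------------------------------------------- pipeline


def test_pipeline_stops_at_first_feasible_model():
    table = generate_cohort(EffectSpec(planted_f2=0.35, seed=4))
    plan = [
        ("recall", "time_played"),  # the planted effect, tested first
        ("recall", "farming_experience"),
        ("recall", "sign_limp"),
    ]
    report = run_study_pipeline(table, plan)
    assert report.feasible_model == "time_played"
    assert len(report.models) == 1


def test_pipeline_corrected_p_consistency_and_order():
    table = generate_cohort(EffectSpec(planted_f2=0.0, seed=6))
    plan = [
        ("recall", "farming_experience"),
        ("recall", "sign_limp"),
        ("recall", "time_played"),
    ]
    report = run_study_pipeline(table, plan)
    raw = [m.p_raw for m in report.models]
    assert [m.p_corrected for m in report.models] == pytest.approx(
        bonferroni_sequential(raw)
    )
    assert [m.test_index for m in report.models] == list(range(1, len(raw) + 1))


def test_pipeline_reports_power_and_skew_for_cohort_size():
    table = generate_cohort(EffectSpec(planted_f2=0.21, seed=2))
    report = run_study_pipeline(table, [("recall", "time_played")])
    assert report.power.v == 61
    assert round(report.power.f2, 2) == 0.21
    assert set(report.skew_tests) == {"accuracy", "recall"}
    assert report.skew_tests["recall"].n == 63


def test_pipeline_group_summaries_for_categorical_predictors():
    table = generate_cohort(EffectSpec(planted_f2=0.0, seed=8))
    report = run_study_pipeline(
        table, [("recall", "farming_experience"), ("recall", "time_played")]
    )
    assert "farming_experience" in report.group_summaries
    assert "time_played" not in report.group_summaries
    labels = {g.group_label for g in report.group_summaries["farming_experience"]}
    assert labels == {"True", "False"}


def test_pipeline_unknown_column_rejected():
    table = generate_cohort(EffectSpec(seed=1))
    with pytest.raises(KeyError, match="no_such_column"):
        run_study_pipeline(table, [("recall", "no_such_column")])
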