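"""Quantitative evaluation pipeline for game-cohort data.

Implements the study's analysis chain over a cohort of participant records:

* arcsine-square-root transformation of percentage scores (variance
  stabilization for proportion data);
* D'Agostino's skewness-based normality test (skewness ``g1``
  standardized through the Johnson SU transformation to an approximate
  normal ``z``);
* post-hoc power analysis for the overall F test of a linear model via
  Cohen's f², using the noncentral-F distribution with noncentrality
  ``f2 * (u + v + 1)``;
* candidate single-predictor ordinary-least-squares models tested in a
  fixed sequence, with sequential Bonferroni correction (the k-th model's
  p-value is multiplied by k) and a stop-at-first-feasible rule;
* a Pearson chi-squared independence test (no continuity correction);
* per-group summaries with a small-sample quality flag (a group mean is
  flagged as a poor estimate when a quartile lies outside the t-based 95%
  confidence limits of the mean);
* Likert response summarization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_SCHEMA",
    "CohortTable",
    "SkewTestResult",
    "PowerSpec",
    "ModelResult",
    "GroupSummary",
    "StudyReport",
    "arcsine_sqrt",
    "dagostino_skew_test",
    "solve_f2",
    "power_from_f2",
    "fit_single_predictor",
    "bonferroni_sequential",
    "chisq_independence",
    "group_summary",
    "likert_summary",
    "run_study_pipeline",
]

# Column kinds of the cohort table ("boolean" | "category" | "continuous").
COHORT_SCHEMA: dict[str, str] = {
    "participant_id": "category",
    "farming_experience": "boolean",
    "years_with_sheep": "continuous",
    "lameness_prevalence_band": "category",
    "sign_uneven_posture": "boolean",
    "sign_shortened_stride": "boolean",
    "sign_quickened_opposite_stride": "boolean",
    "sign_head_nod": "boolean",
    "sign_limp": "boolean",
    "sign_raised_leg": "boolean",
    "sign_reluctance_to_move": "boolean",
    "sign_grazing_on_knees": "boolean",
    "sign_other": "boolean",
    "times_played_before": "category",
    "control_problems": "boolean",
    "observing_type": "category",
    "moving_type": "category",
    "tutorial_completed": "category",
    "pointing_device": "category",
    "time_played": "continuous",
    "accuracy": "continuous",
    "recall": "continuous",
}


@dataclass
class CohortTable:
    """A cohort of participant records plus per-column kind metadata."""

    df: pd.DataFrame
    schema: dict[str, str] = field(default_factory=lambda: dict(COHORT_SCHEMA))

    def __post_init__(self) -> None:
        missing = [c for c in self.schema if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        if self.df["participant_id"].duplicated().any():
            raise ValueError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def kind(self, column: str) -> str:
        try:
            return self.schema[column]
        except KeyError:
            raise KeyError(f"unknown cohort column: {column}") from None


@dataclass(frozen=True)
class SkewTestResult:
    skewness: float  # sample skewness g1 = m3 / m2^(3/2)
    z_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    u: int  # numerator df
    v: int  # denominator df
    alpha: float
    power: float
    f2: float

    def __post_init__(self) -> None:
        if self.u < 1 or self.v < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("need 0 < alpha < power < 1")
        if not self.f2 > 0:
            raise ValueError("f2 must be > 0")


@dataclass(frozen=True)
class ModelResult:
    predictor_name: str
    r2_adj: float
    F: float
    df: tuple[int, int]
    p_raw: float
    p_corrected: Optional[float] = None
    test_index: Optional[int] = None
    n_dropped: int = 0


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    mean: float
    lower_quartile: float
    upper_quartile: float
    ci95_low: float
    ci95_high: float
    poor_estimate: bool


def arcsine_sqrt(p):
    """Variance-stabilizing transform asin(sqrt(p/100)) for percentages."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def dagostino_skew_test(sample: Iterable[float]) -> SkewTestResult:
    """D'Agostino's (1970) skewness test for normality.

    Standardizes the sample skewness with its exact small-sample moments and
    maps it through the Johnson SU transformation to an approximately
    standard-normal z; the p-value is two-sided.  Valid for 8 < n < 46340.
    """
    x = np.asarray(list(sample), dtype=float)
    n = x.size
    if not 8 < n < 46340:
        raise ValueError(f"sample size {n} outside supported range (8, 46340)")
    g1 = float(sps.skew(x, bias=True))
    if g1 == 0.0:
        # exactly symmetric sample: z = 0 by the transformation itself
        # (scipy substitutes y=1 at this point, which would give z != 0)
        z, p = 0.0, 1.0
    else:
        z, p = sps.skewtest(x)
    return SkewTestResult(skewness=g1, z_stat=float(z), p_value=float(p), n=n)


def power_from_f2(f2: float, u: int, v: int, alpha: float) -> float:
    """Power of the overall F test at effect size f² (ncp = f²·(u+v+1))."""
    crit = sps.f.isf(alpha, u, v)
    return float(sps.ncf.sf(crit, u, v, f2 * (u + v + 1)))


def solve_f2(u: int, v: int, alpha: float, power: float) -> float:
    """Effect size f² detectable at the given power (post-hoc power analysis).

    Solves ``P(F'(u, v, ncp=f2·(u+v+1)) > F_crit(1-alpha; u, v)) = power``
    for f² by bracketing root-find to |power error| < 1e-8.
    """
    if u < 1 or v < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    lo, hi = 1e-12, 1000.0
    fn = lambda f2: power_from_f2(f2, u, v, alpha) - power
    if fn(lo) > 0 or fn(hi) < 0:
        raise ArithmeticError("no f2 root in (0, 1000) for the requested power")
    f2 = brentq(fn, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(power_from_f2(f2, u, v, alpha) - power) > 1e-8:
        raise ArithmeticError("power root did not converge to 1e-8")
    return float(f2)


def _design_matrix(cohort: CohortTable, predictor: str, data: pd.DataFrame):
    kind = cohort.kind(predictor)
    x = data[predictor]
    if kind == "continuous":
        mat = x.to_numpy(dtype=float)[:, None]
    else:
        levels = pd.unique(x)
        if len(levels) < 2:
            raise ValueError(f"predictor {predictor!r} is constant (degenerate design)")
        mat = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
    if kind == "continuous" and np.ptp(mat) == 0:
        raise ValueError(f"predictor {predictor!r} is constant (degenerate design)")
    return mat


def fit_single_predictor(
    cohort: CohortTable,
    outcome: str,
    predictor: str,
    transform: bool = True,
) -> ModelResult:
    """OLS of (optionally arcsine-sqrt transformed) outcome on one predictor.

    Missing values are dropped listwise with a logged count.  A categorical
    predictor with k levels contributes k-1 numerator degrees of freedom.
    """
    data = cohort.df[[outcome, predictor]].dropna()
    n_dropped = len(cohort.df) - len(data)
    if n_dropped:
        logger.info(
            "fit_single_predictor(%s ~ %s): dropped %d rows with missing values",
            outcome,
            predictor,
            n_dropped,
        )
    y = data[outcome].to_numpy(dtype=float)
    if transform:
        y = arcsine_sqrt(y)
    exog = sm.add_constant(_design_matrix(cohort, predictor, data))
    res = sm.OLS(y, exog).fit()
    return ModelResult(
        predictor_name=predictor,
        r2_adj=float(res.rsquared_adj),
        F=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p_raw=float(res.f_pvalue),
        n_dropped=n_dropped,
    )


def bonferroni_sequential(p_raw_list: Sequence[float]) -> list[float]:
    """Sequential Bonferroni: the k-th (1-based) p-value is multiplied by k.

    The multiplier counts the models tested up to and including the current
    one, capped at 1.  (The first test is therefore uncorrected.)
    """
    out = []
    for k, p in enumerate(p_raw_list, start=1):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
        out.append(min(1.0, k * p))
    return out


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def group_summary(values: Iterable[float], label: str) -> GroupSummary:
    """Mean, quartiles and t-based 95% CI of the mean for one group.

    The mean is flagged as a poor estimate when the lower quartile falls
    strictly below the lower confidence limit or the upper quartile rises
    strictly above the upper limit — i.e. when between-animal spread
    swamps what the CI claims to pin down at this sample size.
    """
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("group_summary needs at least 2 values")
    mean = float(x.mean())
    q1, q3 = (float(q) for q in np.quantile(x, [0.25, 0.75]))  # linear interpolation
    sem = x.std(ddof=1) / math.sqrt(n)
    half = float(sps.t.ppf(0.975, n - 1) * sem)
    lo, hi = mean - half, mean + half
    return GroupSummary(
        group_label=str(label),
        n=n,
        mean=mean,
        lower_quartile=q1,
        upper_quartile=q3,
        ci95_low=lo,
        ci95_high=hi,
        poor_estimate=bool(q1 < lo or q3 > hi),
    )


LIKERT_LEVELS = ("negative", "neutral", "positive")


def likert_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized percentages of negative/neutral/positive responses.

    ``responses`` has one row per statement and columns for the three
    response levels; empty rows are skipped with a warning.
    """
    counts = responses[list(LIKERT_LEVELS)].astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"skipping statements with no responses: {list(counts.index[empty])}",
            stacklevel=2,
        )
    pct = counts[~empty].div(totals[~empty], axis=0) * 100.0
    return pct


@dataclass
class StudyReport:
    """Structured output of the full evaluation pipeline."""

    n: int
    skew_tests: dict[str, SkewTestResult]
    power: PowerSpec
    models: list[ModelResult]
    feasible_model: Optional[str]
    group_summaries: dict[str, list[GroupSummary]]
    n_accuracy_missing: int = 0

    def to_dict(self) -> dict:
        import dataclasses

        return {
            "n": self.n,
            "skew_tests": {k: dataclasses.asdict(v) for k, v in self.skew_tests.items()},
            "power": dataclasses.asdict(self.power),
            "models": [dataclasses.asdict(m) for m in self.models],
            "feasible_model": self.feasible_model,
            "group_summaries": {
                k: [dataclasses.asdict(g) for g in v]
                for k, v in self.group_summaries.items()
            },
            "n_accuracy_missing": self.n_accuracy_missing,
        }


def run_study_pipeline(
    cohort: CohortTable,
    plan: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    target_power: float = 0.95,
) -> StudyReport:
    """Execute the full evaluation pipeline over a cohort.

    Order of operations: D'Agostino skewness tests of the (transformed)
    accuracy and recall distributions; a power report for the cohort's
    sample size; the planned single-predictor models fitted in sequence with
    sequential Bonferroni correction, stopping after the first model whose
    corrected p-value falls below ``alpha``; per-level group summaries of
    recall for every categorical predictor in the plan.
    """
    if not plan:
        raise ValueError("plan must contain at least one (outcome, predictor) pair")
    for outcome, predictor in plan:
        for col in (outcome, predictor):
            if col not in cohort.df.columns:
                raise KeyError(f"plan references unknown column {col!r}")

    n = len(cohort)
    skew_tests = {}
    acc = cohort.df["accuracy"].dropna()
    n_acc_missing = n - len(acc)
    if n_acc_missing:
        logger.info("excluding %d rows with missing accuracy", n_acc_missing)
    for name, series in (("accuracy", acc), ("recall", cohort.df["recall"].dropna())):
        skew_tests[name] = dagostino_skew_test(arcsine_sqrt(series.to_numpy()))

    v = n - 2  # single continuous or two-level predictor
    power = PowerSpec(
        u=1, v=v, alpha=alpha, power=target_power,
        f2=solve_f2(1, v, alpha, target_power),
    )

    models: list[ModelResult] = []
    feasible: Optional[str] = None
    for k, (outcome, predictor) in enumerate(plan, start=1):
        try:
            res = fit_single_predictor(cohort, outcome, predictor, transform=True)
        except ValueError as exc:
            raise ValueError(f"model {k} ({outcome} ~ {predictor}): {exc}") from exc
        p_corr = bonferroni_sequential([m.p_raw for m in models] + [res.p_raw])[-1]
        res = ModelResult(
            predictor_name=res.predictor_name,
            r2_adj=res.r2_adj,
            F=res.F,
            df=res.df,
            p_raw=res.p_raw,
            p_corrected=p_corr,
            test_index=k,
            n_dropped=res.n_dropped,
        )
        models.append(res)
        if p_corr < alpha:  # stop at the first feasible model
            feasible = predictor
            break

    group_summaries: dict[str, list[GroupSummary]] = {}
    for outcome, predictor in plan:
        if cohort.kind(predictor) in ("boolean", "category"):
            data = cohort.df[[outcome, predictor]].dropna()
            groups = []
            for label, sub in data.groupby(predictor, sort=True, observed=True):
                if len(sub) >= 2:
                    groups.append(
                        group_summary(sub[outcome].to_numpy(dtype=float), str(label))
                    )
            group_summaries[predictor] = groups

    return StudyReport(
        n=n,
        skew_tests=skew_tests,
        power=power,
        models=models,
        feasible_model=feasible,
        group_summaries=group_summaries,
        n_accuracy_missing=n_acc_missing,
    )
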