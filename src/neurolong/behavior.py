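"""Demographic and neuropsychological statistics battery.

Group comparisons of demographics follow a normality gate: Shapiro-Wilk at
alpha = .05 routes a continuous measure to a pooled-variance t-test when
normal and to the Mann-Whitney U otherwise.  Categorical rows use Fisher's
exact test (2x2) or the likelihood-ratio (G) chi-square (RxC); because
printed tables in this literature often carry Pearson X^2 p-values under a
"likelihood ratio" heading, both statistics are returned.  Longitudinal
test scores reuse the piecewise mixed model with a measure-dependent
covariate set, and scaled scores (population mean 10, SD 3) convert to
percentile ranks through the normal CDF after integer rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lme import PiecewiseLME, contrast_table

__all__ = [
    "GroupSummary",
    "NormalityDecision",
    "normality_gate",
    "mann_whitney",
    "fisher_exact",
    "likelihood_ratio_chisq",
    "two_sample_t_from_summary",
    "scaled_score_percentile",
    "behavior_lme",
]


@dataclass
class GroupSummary:
    """Printed mean / SD / n of one measure in one arm."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 2:
            raise ValueError("need sd >= 0 and n >= 2")


@dataclass
class NormalityDecision:
    W: float
    p: float
    normal: bool
    route: str  # "t_test" | "mann_whitney"


def normality_gate(values, alpha: float = 0.05) -> NormalityDecision:
    """Shapiro-Wilk gate deciding parametric vs rank-based comparison."""
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    W, p = stats.shapiro(x)
    normal = p >= alpha
    return NormalityDecision(
        W=float(W), p=float(p), normal=normal,
        route="t_test" if normal else "mann_whitney",
    )


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have n <= 8 and no ties span the
    groups; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.r_[a, b]
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _hypergeom_logpmf(a: int, r1: int, c1: int, n: int) -> float:
    return (
        math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
        + math.lgamma(n - r1 + 1) - math.lgamma(c1 - a + 1)
        - math.lgamma(n - r1 - c1 + a + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, minimum-likelihood rule.

    Sums hypergeometric probabilities (margins fixed) of every table whose
    probability does not exceed the observed one, with a 1e-7 relative
    tolerance on floating-point ties.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = int(t.sum())
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: Fisher test undefined")
    a_obs = int(t[0, 0])
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    logp = np.array([_hypergeom_logpmf(a, r1, c1, n) for a in range(lo, hi + 1)])
    p_obs = logp[a_obs - lo]
    keep = logp <= p_obs + 1e-7
    return float(min(np.exp(logp[keep]).sum(), 1.0))


@dataclass
class GTestResult:
    G: float
    df: int
    p: float
    pearson_x2: float
    pearson_p: float


def likelihood_ratio_chisq(table) -> GTestResult:
    """Likelihood-ratio (G) chi-square for an RxC table.

    ``G = 2 sum O ln(O/E)`` with zero cells contributing 0,
    ``df = (R-1)(C-1)``.  The Pearson X^2 companion is also returned: the
    two agree asymptotically, and published tables sometimes print the
    Pearson p under a likelihood-ratio label.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or min(t.shape) < 2 or np.any(t < 0):
        raise ValueError("need an RxC table (R, C >= 2) of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    E = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / E), 0.0)
    G = float(2.0 * terms.sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    x2 = float(((t - E) ** 2 / E).sum())
    return GTestResult(
        G=G, df=df, p=float(stats.chi2.sf(G, df)),
        pearson_x2=x2, pearson_p=float(stats.chi2.sf(x2, df)),
    )


def two_sample_t_from_summary(
    a: GroupSummary, b: GroupSummary
) -> tuple[float, int, float]:
    """Pooled-variance (Student) t-test from printed summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 <= 0:
        raise ZeroDivisionError("zero pooled variance")
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def scaled_score_percentile(ss: float) -> int:
    """Percentile rank of a scaled score (population mean 10, SD 3).

    The score is rounded to the nearest integer first (the convention in
    normative lookup tables), then ``100 * Phi((ss - 10) / 3)`` is rounded
    to a whole percent; e.g. 8.2 -> 25, 9.8 -> 50.
    """
    if not (1.0 <= ss <= 19.0):
        raise ValueError("scaled scores live in [1, 19]")
    ss_int = int(math.floor(ss + 0.5))
    return int(math.floor(100.0 * stats.norm.cdf((ss_int - 10.0) / 3.0) + 0.5))


_COVARIATE_SETS = {
    "full": {"subject": ("education", "iq"), "longitudinal": ("bdi",)},
    "bdi_only": {"subject": (), "longitudinal": ("bdi",)},
    "none": {"subject": (), "longitudinal": ()},
}


def behavior_lme(
    cohort: pd.DataFrame,
    score_name: str,
    covariate_set: str = "full",
    breakpoint: float | None = None,
) -> tuple[PiecewiseLME, pd.DataFrame]:
    """Piecewise mixed model for one test score plus its contrast table.

    ``covariate_set`` follows the measure-dependent rules: ``"full"``
    (years of education, estimated current IQ, and BDI) for age-adjusted
    cognitive scores, ``"bdi_only"`` for the life-satisfaction scale, and
    ``"none"`` for mood/PTSD measures.  The returned table mirrors the
    five-column layout of the score comparisons: baseline group
    difference, then the four between-group change contrasts.
    """
    if covariate_set not in _COVARIATE_SETS:
        raise ValueError(f"covariate_set must be one of {sorted(_COVARIATE_SETS)}")
    spec = _COVARIATE_SETS[covariate_set]
    est = PiecewiseLME(
        outcome=score_name,
        subject_covariates=spec["subject"],
        longitudinal_covariates=spec["longitudinal"],
        breakpoint=breakpoint,
    ).fit(cohort)
    table = contrast_table(est, include_baseline=True)
    keep = (table["scope"] == "between") | (table["label"] == "baseline")
    order = {"baseline": 0, "tp2_minus_tp1": 1, "tp3_minus_tp2": 2,
             "monotonic": 3, "nonmonotonic": 4}
    table = table[keep].copy()
    table["order"] = table["label"].map(order)
    table = table.sort_values("order").drop(columns="order").reset_index(drop=True)
    table.insert(0, "measure", score_name)
    return est, table
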