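"""Piecewise linear mixed-effects model with a breakpoint and its contrasts.

The model for an outcome :math:`y_{ij}` of subject *i* at visit *j* is

.. math::

    y_{ij} = \\beta_1 + \\beta_2 t_{ij} + \\beta_3 (t_{ij}-\\tilde t)H(t_{ij}-\\tilde t)
        + \\beta_4 S_i + \\beta_5 S_i t_{ij}
        + \\beta_6 S_i (t_{ij}-\\tilde t)H(t_{ij}-\\tilde t)
        + \\beta_7 A_i + \\beta_8 \\bar B_i + \\beta_9 (B_{ij}-\\bar B_i)
        + b_i + e_{ij},

where :math:`\\tilde t` is the breakpoint (average mid-study visit time),
:math:`H` the Heaviside step, :math:`S_i` the treatment indicator,
:math:`A_i` a subject-level covariate (age), :math:`\\bar B_i` and
:math:`B_{ij}-\\bar B_i` the between/within decomposition of a time-varying
covariate, :math:`b_i \\sim N(0,\\sigma_b^2)` a random intercept and
:math:`e_{ij} \\sim N(0,\\sigma_e^2)` the residual.  Estimation is by full
maximum likelihood (not REML) so that bootstrap refits compare likelihoods
on a common footing.

Hypotheses about change between nominal timepoints are linear contrasts of
the slope coefficients evaluated at the cohort-average visit times, tested
with Wald Z statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._engine import (
    SingularDesignError,
    fit_random_intercept_ml,
    group_sizes_from_sorted,
)

logger = logging.getLogger("neurolong")

__all__ = [
    "PiecewiseLME",
    "PiecewiseLMEFit",
    "ContrastSpec",
    "ContrastResult",
    "fit_piecewise_lme",
    "center_covariate",
    "build_contrast",
    "test_contrast",
    "contrast_table",
    "CONTRAST_LABELS",
    "CONTRAST_SCOPES",
    "SingularDesignError",
]

CONTRAST_LABELS = ("tp2_minus_tp1", "tp3_minus_tp2", "monotonic", "nonmonotonic")
CONTRAST_SCOPES = ("within_control", "within_treatment", "between")


@dataclass
class PiecewiseLMEFit:
    """Fitted fixed effects, variance components and design summaries."""

    feature_names: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    sigma_b2: float
    sigma_e2: float
    t_break: float
    t_bar: dict[int, float]
    loglik: float
    n_subjects: int
    n_obs: int
    boundary: bool = False
    outcome: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.feature_names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se}, index=self.feature_names
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "feature_names": list(self.feature_names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "sigma_b2": self.sigma_b2,
            "sigma_e2": self.sigma_e2,
            "t_break": self.t_break,
            "t_bar": {str(k): v for k, v in self.t_bar.items()},
            "loglik": self.loglik,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }


@dataclass
class ContrastSpec:
    """A weight vector over the fixed effects plus its provenance."""

    label: str
    scope: str
    weights: np.ndarray
    feature_names: list[str] = field(default_factory=list)


@dataclass
class ContrastResult:
    """Wald test of a single linear contrast."""

    estimate: float
    se: float
    z: float
    p: float
    label: str = ""
    scope: str = ""


def center_covariate(
    records: pd.DataFrame,
    covariate: str,
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Split a time-varying covariate into subject-mean and deviation parts.

    Rows with a missing covariate value are dropped (with a logged count):
    a visit without the covariate cannot enter the fit, but the subject's
    other visits can.  Returns a copy of ``records`` restricted to usable
    rows, with ``{covariate}_between`` and ``{covariate}_within`` columns
    appended; within-parts sum to zero per subject by construction.
    """
    if covariate not in records.columns:
        raise KeyError(f"covariate {covariate!r} not in records")
    missing = records[covariate].isna()
    if missing.any():
        logger.info(
            "excluding %d visit(s) with missing %s (listwise by visit)",
            int(missing.sum()),
            covariate,
        )
    out = records.loc[~missing].copy()
    mean = out.groupby(subject_col)[covariate].transform("mean")
    out[f"{covariate}_between"] = mean
    out[f"{covariate}_within"] = out[covariate] - mean
    return out


class PiecewiseLME(BaseEstimator):
    """Random-intercept piecewise linear model, scikit-learn style.

    Parameters
    ----------
    outcome
        Column of the long-format visit table to model.
    subject_covariates
        Columns entering as subject-level fixed effects (default ``("age",)``).
    longitudinal_covariates
        Time-varying columns; each contributes a between-subject mean and a
        within-subject deviation column (default ``("bdi",)``).
    breakpoint
        Slope-change time in weeks.  ``None`` uses the average observed
        time of the middle visit (timepoint 2), the study's convention.

    The long table must carry ``subject``, ``group`` (0 control /
    1 treatment), ``timepoint`` (1, 2, 3), ``time`` (weeks from baseline)
    and the outcome/covariate columns.

    Fitted attributes: ``beta_``, ``beta_cov_``, ``sigma_b2_``,
    ``sigma_e2_``, ``loglik_``, ``t_break_``, ``t_bar_``,
    ``feature_names_``, ``n_subjects_``, ``n_obs_``, ``result_``.
    """

    def __init__(
        self,
        outcome: str | None = None,
        subject_covariates: tuple[str, ...] = ("age",),
        longitudinal_covariates: tuple[str, ...] = ("bdi",),
        breakpoint: float | None = None,
    ):
        self.outcome = outcome
        self.subject_covariates = subject_covariates
        self.longitudinal_covariates = longitudinal_covariates
        self.breakpoint = breakpoint

    # -- design construction -------------------------------------------------
    def _prepare(self, data: pd.DataFrame, outcome: str):
        required = {"subject", "group", "timepoint", "time", outcome}
        required |= set(self.subject_covariates)
        required |= set(self.longitudinal_covariates)
        missing_cols = required - set(data.columns)
        if missing_cols:
            raise KeyError(f"missing columns: {sorted(missing_cols)}")
        d = data.copy()
        n_before = len(d)
        d = d.loc[d[outcome].notna()]
        dropped = n_before - len(d)
        if dropped:
            logger.info("excluding %d visit(s) with missing outcome %s", dropped, outcome)
        for cov in self.subject_covariates:
            d = d.loc[d[cov].notna()]
        for cov in self.longitudinal_covariates:
            d = center_covariate(d, cov)
        if d["subject"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        d = d.sort_values(["subject", "time"], kind="stable").reset_index(drop=True)

        tp = d["timepoint"].to_numpy()
        t = d["time"].to_numpy(float)
        if self.breakpoint is not None:
            t_break = float(self.breakpoint)
        else:
            if not np.any(tp == 2):
                raise ValueError("no timepoint-2 visits to locate the breakpoint")
            t_break = float(t[tp == 2].mean())
        t_bar = {1: 0.0}
        for j in (2, 3):
            t_bar[j] = float(t[tp == j].mean()) if np.any(tp == j) else np.nan
        if self.breakpoint is not None:
            t_bar[2] = t_break
        if not (t.min() < t_break < t.max()):
            raise ValueError(
                f"breakpoint {t_break:.2f} must lie strictly inside the "
                f"observed time range [{t.min():.2f}, {t.max():.2f}]"
            )

        S = d["group"].to_numpy(float)
        hinge = np.clip(t - t_break, 0.0, None)
        cols: dict[str, np.ndarray] = {
            "intercept": np.ones_like(t),
            "time": t,
            "hinge": hinge,
            "group": S,
            "group_time": S * t,
            "group_hinge": S * hinge,
        }
        for cov in self.subject_covariates:
            cols[cov] = d[cov].to_numpy(float)
        for cov in self.longitudinal_covariates:
            cols[f"{cov}_between"] = d[f"{cov}_between"].to_numpy(float)
            cols[f"{cov}_within"] = d[f"{cov}_within"].to_numpy(float)
        # constant covariate columns carry no information and would only make
        # the design singular (e.g. a covariate recorded once per cohort)
        structural = {"intercept", "time", "hinge", "group", "group_time", "group_hinge"}
        for name in [k for k in cols if k not in structural]:
            if np.ptp(cols[name]) == 0.0:
                logger.info("dropping constant covariate column %s", name)
                del cols[name]
        X = np.column_stack(list(cols.values()))
        codes = pd.factorize(d["subject"], sort=False)[0]
        starts, sizes = group_sizes_from_sorted(codes)
        y = d[outcome].to_numpy(float)
        return d, X, list(cols.keys()), y, starts, sizes, t_break, t_bar

    # -- estimator API -------------------------------------------------------
    def fit(self, data: pd.DataFrame, outcome: str | None = None) -> "PiecewiseLME":
        outcome = outcome or self.outcome
        if outcome is None:
            raise ValueError("no outcome specified")
        d, X, names, y, starts, sizes, t_break, t_bar = self._prepare(data, outcome)
        res = fit_random_intercept_ml(X, y, starts, sizes)
        self.data_ = d
        self.feature_names_ = names
        self.beta_ = res["beta"]
        self.beta_cov_ = res["beta_cov"]
        self.sigma_b2_ = res["sigma_b2"]
        self.sigma_e2_ = res["sigma_e2"]
        self.loglik_ = res["loglik"]
        self.boundary_ = res["boundary"]
        self.t_break_ = t_break
        self.t_bar_ = t_bar
        self.n_subjects_ = int(sizes.size)
        self.n_obs_ = int(res["n_obs"])
        self.result_ = PiecewiseLMEFit(
            feature_names=names,
            beta=self.beta_,
            beta_cov=self.beta_cov_,
            sigma_b2=self.sigma_b2_,
            sigma_e2=self.sigma_e2_,
            t_break=t_break,
            t_bar=t_bar,
            loglik=self.loglik_,
            n_subjects=self.n_subjects_,
            n_obs=self.n_obs_,
            boundary=self.boundary_,
            outcome=outcome,
        )
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (random intercept set to 0)."""
        fit = self.result_
        t = data["time"].to_numpy(float)
        S = data["group"].to_numpy(float)
        hinge = np.clip(t - fit.t_break, 0.0, None)
        known = {
            "intercept": np.ones_like(t),
            "time": t,
            "hinge": hinge,
            "group": S,
            "group_time": S * t,
            "group_hinge": S * hinge,
        }
        cols = [
            known[name] if name in known else data[name].to_numpy(float)
            for name in fit.feature_names
        ]
        return np.column_stack(cols) @ fit.beta


def fit_piecewise_lme(
    records: pd.DataFrame,
    outcome: str,
    subject_covariates: tuple[str, ...] = ("age",),
    longitudinal_covariates: tuple[str, ...] = ("bdi",),
    breakpoint: float | None = None,
) -> PiecewiseLMEFit:
    """Functional wrapper over :class:`PiecewiseLME`."""
    est = PiecewiseLME(
        outcome=outcome,
        subject_covariates=subject_covariates,
        longitudinal_covariates=longitudinal_covariates,
        breakpoint=breakpoint,
    )
    return est.fit(records).result_


def _as_result(fit) -> PiecewiseLMEFit:
    if isinstance(fit, PiecewiseLME):
        return fit.result_
    return fit


def build_contrast(fit, label: str, scope: str) -> ContrastSpec:
    """Contrast weights for change hypotheses at cohort-average times.

    With ``d1 = t_break - t_bar[1]`` (baseline fixed at 0) and
    ``d2 = t_bar[3] - t_break``:

    * ``tp2_minus_tp1``: ``d1`` on the pre-break slope(s);
    * ``tp3_minus_tp2``: ``d2`` on the post-break slope(s), i.e. the sum of
      the base slope and the hinge slope change;
    * ``monotonic``: the sum of the two (net change baseline -> final);
    * ``nonmonotonic``: the difference (rise-then-return component).

    ``scope`` picks which slope family carries the weights: control
    (``time``/``hinge``), treatment (both families) or the group-by-time
    interaction only (``between``).
    """
    fit = _as_result(fit)
    if label not in CONTRAST_LABELS:
        raise ValueError(f"unknown contrast label {label!r}")
    if scope not in CONTRAST_SCOPES:
        raise ValueError(f"unknown contrast scope {scope!r}")
    names = fit.feature_names
    t_bar = fit.t_bar
    d1 = fit.t_break - t_bar.get(1, 0.0)
    d2 = t_bar[3] - fit.t_break
    if not np.isfinite(d2) or d2 <= 0:
        raise ValueError("final-visit average time not recorded or invalid")

    w = np.zeros(len(names))

    def add(name: str, value: float) -> None:
        w[names.index(name)] += value

    def seg_tp2(slope: str, hinge: str, sign: float = 1.0) -> None:
        add(slope, sign * d1)

    def seg_tp3(slope: str, hinge: str, sign: float = 1.0) -> None:
        add(slope, sign * d2)
        add(hinge, sign * d2)

    families = {
        "within_control": [("time", "hinge")],
        "within_treatment": [("time", "hinge"), ("group_time", "group_hinge")],
        "between": [("group_time", "group_hinge")],
    }[scope]
    for slope, hinge in families:
        if label in ("tp2_minus_tp1", "monotonic"):
            seg_tp2(slope, hinge)
        if label in ("tp3_minus_tp2", "monotonic"):
            seg_tp3(slope, hinge)
        if label == "nonmonotonic":
            seg_tp2(slope, hinge)
            seg_tp3(slope, hinge, sign=-1.0)
    return ContrastSpec(label=label, scope=scope, weights=w, feature_names=list(names))


def test_contrast(fit, contrast: ContrastSpec | np.ndarray) -> ContrastResult:
    """Wald test of ``w' beta`` against 0 with a standard-normal reference."""
    fit = _as_result(fit)
    if isinstance(contrast, ContrastSpec):
        w, label, scope = contrast.weights, contrast.label, contrast.scope
    else:
        w, label, scope = np.asarray(contrast, float), "", ""
    if w.shape != (len(fit.feature_names),):
        raise ValueError("contrast length does not match the fixed effects")
    if not np.any(w):
        raise ValueError("degenerate contrast: all weights zero")
    est = float(w @ fit.beta)
    var = float(w @ fit.beta_cov @ w)
    if var <= 0:
        raise ZeroDivisionError("contrast has zero variance; test undefined")
    se = float(np.sqrt(var))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ContrastResult(estimate=est, se=se, z=z, p=max(p, np.finfo(float).tiny),
                          label=label, scope=scope)


def contrast_table(fit, include_baseline: bool = False) -> pd.DataFrame:
    """Tidy table of every (label, scope) Wald test for one fitted model."""
    fit = _as_result(fit)
    rows = []
    if include_baseline:
        w = np.zeros(len(fit.feature_names))
        w[fit.feature_names.index("group")] = 1.0
        r = test_contrast(fit, w)
        rows.append(("baseline", "between", r.estimate, r.se, r.z, r.p))
    for scope in CONTRAST_SCOPES:
        for label in CONTRAST_LABELS:
            spec = build_contrast(fit, label, scope)
            r = test_contrast(fit, spec)
            rows.append((label, scope, r.estimate, r.se, r.z, r.p))
    return pd.DataFrame(
        rows, columns=["label", "scope", "estimate", "se", "z", "p"]
    )
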