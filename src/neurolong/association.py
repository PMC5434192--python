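"""Brain-behaviour association models.

Does improvement on a behavioural score co-occur, within subject, with
change in a brain measure?  The behavioural score is first residualized
cohort-wide on nuisance covariates (age, education, estimated IQ, mood),
then enters the piecewise mixed model as an additional between/within
covariate pair; the Wald test of the *within-subject* coefficient is the
association statistic.  For regions whose trajectories rise then return to
baseline, the outcome is reflected across its mid-study value first
(``nonmonotonic`` mode) so a monotone behavioural gain can align with a
rise-then-return brain trajectory.  Seed-based connectivity maps repeat
the test per seed with a Bonferroni family threshold across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lme import ContrastResult, PiecewiseLME, test_contrast
from .posthoc import reflect_tp3_frame

__all__ = [
    "AugmentedModelSpec",
    "residualize_score",
    "association_test",
    "seed_association_map",
    "bonferroni_threshold",
]

DEFAULT_RESIDUALIZATION = ("age", "education", "iq", "bdi")


@dataclass
class AugmentedModelSpec:
    """How a behavioural score augments the base piecewise model."""

    score: str
    residualization_set: tuple[str, ...] = DEFAULT_RESIDUALIZATION
    subject_covariates: tuple[str, ...] = ("age",)
    longitudinal_covariates: tuple[str, ...] = ("bdi",)


def residualize_score(scores, covariates) -> np.ndarray:
    """Residuals of a score after ordinary least squares on covariates.

    The adjustment is done once, cohort-wide, with an intercept; rows are
    assumed complete.  Residuals are orthogonal to every covariate (and
    mean zero), but within-subject temporal structure is untouched since
    each visit keeps its own residual.
    """
    y = np.asarray(scores, float)
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient adjustment design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def association_test(
    cohort: pd.DataFrame,
    outcome: str,
    spec: AugmentedModelSpec,
    mode: str = "monotonic",
) -> ContrastResult:
    """Wald test of the within-subject score coefficient.

    ``mode="nonmonotonic"`` reflects the outcome (not the score) at the
    final visit before fitting.  A positive estimate means score gains
    co-occur with outcome increases (monotonic mode) or with
    rise-then-return outcome excursions (nonmonotonic mode).
    """
    if mode not in ("monotonic", "nonmonotonic"):
        raise ValueError("mode must be 'monotonic' or 'nonmonotonic'")
    d = cohort.copy()
    needed = [spec.score, *spec.residualization_set]
    d = d.dropna(subset=[c for c in needed if c in d.columns])
    adj_name = f"{spec.score}_adj"
    resid_cols = [c for c in spec.residualization_set if c in d.columns]
    if resid_cols:
        d[adj_name] = residualize_score(d[spec.score], d[resid_cols])
    else:
        d[adj_name] = d[spec.score] - d[spec.score].mean()
    if mode == "nonmonotonic":
        d = reflect_tp3_frame(d, outcome)
    est = PiecewiseLME(
        outcome=outcome,
        subject_covariates=spec.subject_covariates,
        longitudinal_covariates=(*spec.longitudinal_covariates, adj_name),
    ).fit(d)
    w = np.zeros(len(est.feature_names_))
    w[est.feature_names_.index(f"{adj_name}_within")] = 1.0
    res = test_contrast(est, w)
    res.label = f"{spec.score}_within"
    res.scope = mode
    return res


def bonferroni_threshold(alpha: float, n_seeds: int) -> float:
    """Family threshold correcting for the number of seeds: alpha / n."""
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    return alpha / n_seeds


def seed_association_map(
    edges: np.ndarray,
    design: pd.DataFrame,
    seeds: list[int],
    spec: AugmentedModelSpec,
    mode: str = "monotonic",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score association for every connection of every seed ROI.

    ``edges`` is the standardized (n_scans, n_roi, n_roi) stack aligned
    with ``design`` rows.  For each seed, each seed-to-ROI edge becomes an
    outcome in the augmented model; the familywise threshold is
    ``alpha / n_seeds`` (Bonferroni across seeds).
    """
    if not seeds:
        raise ValueError("seed list is empty")
    edges = np.asarray(edges, float)
    n_roi = edges.shape[1]
    for s in seeds:
        if not (0 <= s < n_roi):
            raise KeyError(f"unknown seed index {s}")
    threshold = bonferroni_threshold(alpha, len(seeds))
    rows = []
    for s in seeds:
        for j in range(n_roi):
            if j == s:
                continue
            d = design.copy()
            d["edge"] = edges[:, s, j]
            res = association_test(d, "edge", spec, mode=mode)
            rows.append(
                {
                    "seed": s,
                    "roi": j,
                    "estimate": res.estimate,
                    "se": res.se,
                    "z": res.z,
                    "p": res.p,
                    "family_threshold": threshold,
                    "significant": res.p < threshold,
                }
            )
    return pd.DataFrame(rows)
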