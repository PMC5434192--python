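"""Single-subject change classification, effect sizes, reflection transform.

After the group-level models flag a region, three post hoc questions
remain: (1) are the group effects carried by a few outliers?  Answered by
counting subjects whose per-visit changes fall outside the mean +/- 2 SD
band of the *other* training arm's change distribution (about 4.6% of a
matched null would be flagged by chance).  (2) How big is the effect?
Covariate-adjusted group trajectory changes, absolute and as percent of
the group baseline mean.  (3) Is a nonmonotonic (rise-then-return)
trajectory associated with behaviour?  The reflection transform maps the
final visit across the mid-study axis, ``y3 -> 2 y2 - y3``, turning a
perfectly nonmonotonic series into a monotonic one so the standard
association machinery applies; the transform is an involution on TP3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lme import PiecewiseLME

logger = logging.getLogger("neurolong")

__all__ = [
    "classify_individual_changes",
    "effect_size_region",
    "reflect_tp3",
    "reflect_tp3_frame",
]

_DELTAS = ("delta_12", "delta_23", "delta_monotonic", "delta_nonmono")


def _wide_deltas(cohort: pd.DataFrame, region: str) -> pd.DataFrame:
    wide = cohort.pivot_table(
        index=["subject", "group"], columns="timepoint", values=region, aggfunc="first"
    )
    wide = wide.reindex(columns=[1, 2, 3]).reset_index()
    wide.columns = ["subject", "group", "y1", "y2", "y3"]
    wide["delta_12"] = wide["y2"] - wide["y1"]
    wide["delta_23"] = wide["y3"] - wide["y2"]
    wide["delta_monotonic"] = wide["y3"] - wide["y1"]
    wide["delta_nonmono"] = (wide["y2"] - wide["y1"]) - (wide["y3"] - wide["y2"])
    return wide


def classify_individual_changes(
    cohort: pd.DataFrame,
    region: str,
    reference_group: int = 0,
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Flag subjects whose change falls outside the other arm's 2 SD band.

    For each change type (TP1->TP2, TP2->TP3, monotonic TP3-TP1,
    nonmonotonic (TP2-TP1)-(TP3-TP2)) the band is
    ``mean +/- n_sd * SD`` of the ``reference_group`` subjects' changes
    (sample SD, n-1); subjects of the *other* arm are flagged when their
    change lies strictly outside the band.  A delta is absent (and never
    flagged) when one of its visits is missing.
    """
    wide = _wide_deltas(cohort, region)
    ref = wide[wide["group"] == reference_group]
    test = wide[wide["group"] != reference_group].copy()
    test["region"] = region
    for col in _DELTAS:
        ref_vals = ref[col].dropna()
        if len(ref_vals) < 2:
            raise ValueError(
                f"reference group too small for {col} ({len(ref_vals)} changes)"
            )
        lo = ref_vals.mean() - n_sd * ref_vals.std(ddof=1)
        hi = ref_vals.mean() + n_sd * ref_vals.std(ddof=1)
        # strict inequality: a change exactly on the band edge is not flagged
        test[f"flag_{col[6:]}"] = (test[col] < lo) | (test[col] > hi)
        test.loc[test[col].isna(), f"flag_{col[6:]}"] = False
    cols = ["subject", "group", "region", "y1", "y2", "y3", *_DELTAS]
    cols += [f"flag_{c[6:]}" for c in _DELTAS]
    return test[cols].reset_index(drop=True)


def effect_size_region(
    cohort: pd.DataFrame,
    region: str,
    group: int = 1,
    pattern: str = "monotonic",
    fit: PiecewiseLME | None = None,
    subject_covariates: tuple[str, ...] = ("age",),
    longitudinal_covariates: tuple[str, ...] = ("bdi",),
) -> tuple[float, float]:
    """Covariate-adjusted change and percent-of-baseline for one region.

    The adjusted group trajectory is the fitted piecewise model evaluated
    for the requested group at the cohort covariate means, at the average
    visit times.  ``pattern`` picks the change window: ``"tp2_minus_tp1"``,
    ``"tp3_minus_tp2"``, ``"monotonic"`` (final minus baseline) or
    ``"nonmonotonic"`` (mid-study excursion from baseline, the relevant
    window when the trajectory returns toward baseline).  Percent change
    normalises by the group's observed baseline mean.
    """
    if fit is None:
        fit = PiecewiseLME(
            outcome=region,
            subject_covariates=subject_covariates,
            longitudinal_covariates=longitudinal_covariates,
        ).fit(cohort)
    res = fit.result_
    names = res.feature_names
    beta = res.beta
    used = fit.data_

    def traj(t: float) -> float:
        hinge = max(t - res.t_break, 0.0)
        v = {
            "intercept": 1.0,
            "time": t,
            "hinge": hinge,
            "group": float(group),
            "group_time": group * t,
            "group_hinge": group * hinge,
        }
        x = np.array(
            [
                v.get(name, used[name].mean() if name in used else 0.0)
                for name in names
            ]
        )
        # within-subject covariate columns average to zero by construction
        for k, name in enumerate(names):
            if name.endswith("_within"):
                x[k] = 0.0
        return float(x @ beta)

    y1 = traj(res.t_bar.get(1, 0.0))
    y2 = traj(res.t_break)
    y3 = traj(res.t_bar[3])
    changes = {
        "tp2_minus_tp1": y2 - y1,
        "tp3_minus_tp2": y3 - y2,
        "monotonic": y3 - y1,
        "nonmonotonic": y2 - y1,
    }
    if pattern not in changes:
        raise ValueError(f"unknown pattern {pattern!r}")
    abs_change = changes[pattern]
    baseline = cohort.loc[
        (cohort["group"] == group) & (cohort["timepoint"] == 1), region
    ].mean()
    if not np.isfinite(baseline) or baseline == 0:
        raise ZeroDivisionError("group baseline mean is zero or undefined")
    return abs_change, 100.0 * abs_change / baseline


def reflect_tp3(y1: float, y2: float, y3: float) -> tuple[float, float, float]:
    """Reflect the final visit across the mid-study value: ``y3 -> 2 y2 - y3``."""
    for v in (y1, y2, y3):
        if v is None or not np.isfinite(v):
            raise ValueError("reflection needs all three timepoints")
    return (y1, y2, 2.0 * y2 - y3)


def reflect_tp3_frame(cohort: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Apply the TP3 reflection per subject on a long visit table.

    TP3 rows of subjects lacking a TP2 value cannot be reflected and are
    dropped (with a logged count); subjects without a TP3 visit pass
    through unchanged.
    """
    out = cohort.copy()
    tp2 = (
        out[out["timepoint"] == 2]
        .dropna(subset=[outcome])
        .set_index("subject")[outcome]
    )
    is_tp3 = out["timepoint"] == 3
    has_tp2 = out["subject"].isin(tp2.index)
    orphan = is_tp3 & ~has_tp2
    if orphan.any():
        logger.info(
            "dropping %d final-visit row(s) without a mid-study value to reflect over",
            int(orphan.sum()),
        )
        out = out.loc[~orphan].copy()
        is_tp3 = out["timepoint"] == 3
    y2 = out["subject"].map(tp2)
    out.loc[is_tp3, outcome] = 2.0 * y2[is_tp3] - out.loc[is_tp3, outcome]
    return out
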