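"""Synthetic two-arm longitudinal cohorts with known generative truth.

Emulates the design of an 8-week cognitive-training trial in chronic TBI:
two arms (strategy-based treatment vs knowledge-based active control),
three visits at nominally 0 / 9 / 21 weeks with per-subject timing jitter,
per-timepoint attrition, a subject random intercept, piecewise-linear group
trajectories with a slope change at the mid-study visit, and age/BDI
covariates.  Outcomes are drawn *exactly* from the piecewise
random-intercept model so that estimator recovery is testable against a
known truth.

Scan simulation provides ROI-by-frame time series with a known latent
covariance plus motion traces (framewise displacement, standardized DVARS)
contaminated by spike artifacts, feeding the connectivity and network-
statistics stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "SpikeParams",
    "ScanSimulation",
    "generate_cohort",
    "generate_scan",
    "DEFAULT_BETA",
]

#: Generative fixed effects, in model order
#: (intercept, time, hinge, group, group_time, group_hinge,
#:  age, bdi_between, bdi_within).  Units: mm of cortical thickness and
#: weeks.  The treatment trajectory rises 0.012 mm/week before the
#: breakpoint and falls back after it (net post-break slope -0.012), i.e. a
#: ~0.11 mm nonmonotonic excursion on a 2.5 mm baseline, the magnitude the
#: study design targets; age and depressive-symptom effects are small and
#: negative.
DEFAULT_BETA = (2.5, 0.0, 0.0, 0.0, 0.012, -0.024, -0.002, -0.002, -0.001)

BETA_NAMES = (
    "intercept",
    "time",
    "hinge",
    "group",
    "group_time",
    "group_hinge",
    "age",
    "bdi_between",
    "bdi_within",
)


@dataclass
class CohortParams:
    """Stated world of the synthetic trial.

    Defaults mirror the study design: 31 treatment / 29 control enrolled,
    visits at 0, 9 and 21 weeks with observed jitter SDs of about 0.8 and
    1.6 weeks, and per-timepoint retention matching the reported structural
    scan counts (treatment 29/27/17 of 31, control 28/24/23 of 29).
    """

    n_treatment: int = 31
    n_control: int = 29
    visit_times_weeks: tuple[float, float, float] = (0.0, 9.0, 21.0)
    time_jitter_sd: tuple[float, float, float] = (0.0, 0.8, 1.6)
    retention_treatment: tuple[float, float, float] = (29 / 31, 27 / 31, 17 / 31)
    retention_control: tuple[float, float, float] = (28 / 29, 24 / 29, 23 / 29)
    beta: tuple[float, ...] = DEFAULT_BETA
    sigma_b: float = 0.12
    sigma_e: float = 0.05
    breakpoint: float | None = None  # None -> nominal mid-study visit time
    age_mean: float = 40.0
    age_sd: float = 12.0
    bdi_mean: float = 18.0
    bdi_sd: float = 10.0
    bdi_visit_sd: float = 3.0
    monotone_dropout: bool = False
    outcome_name: str = "thickness"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatment < 1 or self.n_control < 1:
            raise ValueError("group sizes must be positive")
        t = np.asarray(self.visit_times_weeks, float)
        if t.size != 3 or np.any(np.diff(t) <= 0):
            raise ValueError("visit times must be three strictly increasing values")
        for r in (*self.retention_treatment, *self.retention_control):
            if not (0.0 < r <= 1.0):
                raise ValueError("retention fractions must lie in (0, 1]")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be nonnegative")
        if len(self.beta) != 9:
            raise ValueError("beta must have 9 entries")

    @property
    def t_break(self) -> float:
        return self.visit_times_weeks[1] if self.breakpoint is None else self.breakpoint


@dataclass
class SpikeParams:
    """Motion-spike contamination of a simulated scan."""

    rate: float = 0.1
    fd_scale: float = 0.5
    dvars_jump: float = 2.0
    signal_scale: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("spike rate must be in [0, 1]")


@dataclass
class ScanSimulation:
    """One simulated resting-state scan with aligned motion traces."""

    roi_timeseries: np.ndarray  # frames x n_roi
    motion_fd: np.ndarray
    motion_dvars: np.ndarray
    latent_covariance: np.ndarray
    tr_ms: float = 2000.0
    scan_id: str = ""
    subject_id: str = ""
    timepoint: int = 0

    def __post_init__(self) -> None:
        n = self.roi_timeseries.shape[0]
        if len(self.motion_fd) != n or len(self.motion_dvars) != n:
            raise ValueError("motion traces must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.roi_timeseries.shape[0]


def _visit_times(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered visit times, truncated so ordering is preserved; TP1 at 0."""
    nominal = np.asarray(params.visit_times_weeks, float)
    sd = np.asarray(params.time_jitter_sd, float)
    t = nominal + rng.standard_normal(3) * sd
    t[0] = 0.0
    for j in (1, 2):
        t[j] = max(t[j], t[j - 1] + 0.5)
    return t


def _retained(retention, monotone: bool, rng: np.random.Generator) -> np.ndarray:
    r = np.asarray(retention, float)
    u = rng.uniform(size=3)
    if not monotone:
        return u < r
    ratios = np.minimum(r / np.r_[1.0, r[:-1]], 1.0)
    return np.cumprod(u < ratios).astype(bool)


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort; returns the long visit table and the truth record.

    Outcomes satisfy ``y = X beta + b_i + e`` exactly, with the hinge term
    active only past the breakpoint and the between-subject BDI covariate
    equal to each subject's mean over their *retained* visits (so that
    covariate centering in the estimator reproduces the generative
    columns).  The single seed fans out into per-subject substreams, so a
    subset of subjects is reproducible independently of cohort size.
    """
    root = np.random.SeedSequence(params.seed)
    n_total = params.n_treatment + params.n_control
    streams = [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n_total)]
    beta = dict(zip(BETA_NAMES, params.beta))
    t_break = params.t_break

    rows = []
    for i, rng in enumerate(streams):
        group = 1 if i < params.n_treatment else 0
        subject = f"S{i + 1:03d}"
        retention = (
            params.retention_treatment if group else params.retention_control
        )
        age = params.age_mean + params.age_sd * rng.standard_normal()
        bdi_center = max(
            0.0, params.bdi_mean + params.bdi_sd * rng.standard_normal()
        )
        times = _visit_times(params, rng)
        present = _retained(retention, params.monotone_dropout, rng)
        b_i = params.sigma_b * rng.standard_normal()
        bdi = np.maximum(
            0.0, bdi_center + params.bdi_visit_sd * rng.standard_normal(3)
        )
        if not present.any():
            continue
        bdi_bar = float(bdi[present].mean())
        for j in range(3):
            if not present[j]:
                continue
            t = times[j]
            hinge = max(t - t_break, 0.0)
            mean = (
                beta["intercept"]
                + beta["time"] * t
                + beta["hinge"] * hinge
                + beta["group"] * group
                + beta["group_time"] * group * t
                + beta["group_hinge"] * group * hinge
                + beta["age"] * age
                + beta["bdi_between"] * bdi_bar
                + beta["bdi_within"] * (bdi[j] - bdi_bar)
            )
            y = mean + b_i + params.sigma_e * rng.standard_normal()
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "timepoint": j + 1,
                    "time": t,
                    "age": age,
                    "bdi": bdi[j],
                    params.outcome_name: y,
                }
            )
    cohort = pd.DataFrame(rows)
    truth = {
        "beta": dict(zip(BETA_NAMES, params.beta)),
        "sigma_b": params.sigma_b,
        "sigma_e": params.sigma_e,
        "t_break": t_break,
        "seed": params.seed,
        "params": dataclasses.asdict(params),
    }
    return cohort, truth


def generate_scan(
    latent_cov: np.ndarray,
    n_frames: int,
    spike_params: SpikeParams | None = None,
    seed: int = 0,
    tr_ms: float = 2000.0,
    scan_id: str = "",
    subject_id: str = "",
    timepoint: int = 0,
) -> ScanSimulation:
    """Simulate ROI time series with known covariance plus motion traces.

    Clean frames are iid Gaussian with the requested latent covariance.
    Spike-contaminated frames (Bernoulli ``spike_params.rate``) receive
    framewise displacement pushed above the 0.5 mm censoring threshold, a
    DVARS jump, and a large additive signal perturbation; clean frames stay
    strictly below both default censoring thresholds.
    """
    latent_cov = np.asarray(latent_cov, float)
    if latent_cov.ndim != 2 or latent_cov.shape[0] != latent_cov.shape[1]:
        raise ValueError("latent covariance must be square")
    if not np.allclose(latent_cov, latent_cov.T, atol=1e-10):
        raise ValueError("latent covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(latent_cov)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ValueError("latent covariance is not positive semidefinite")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    spike_params = spike_params or SpikeParams(rate=0.0)
    rng = np.random.default_rng(seed)
    n_roi = latent_cov.shape[0]

    # eigh-based square root tolerates exact semidefiniteness
    vals, vecs = np.linalg.eigh(latent_cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    ts = rng.standard_normal((n_frames, n_roi)) @ root.T

    fd = np.minimum(np.abs(rng.normal(0.15, 0.07, n_frames)), 0.45)
    dvars = np.clip(rng.normal(1.0, 0.2, n_frames), 0.2, 1.7)
    spikes = rng.uniform(size=n_frames) < spike_params.rate
    if spikes.any():
        k = int(spikes.sum())
        fd[spikes] = 0.5 + rng.exponential(spike_params.fd_scale, k)
        dvars[spikes] += spike_params.dvars_jump
        sd = ts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        ts[spikes] += (
            rng.standard_normal((k, n_roi)) * sd * spike_params.signal_scale
        )
    return ScanSimulation(
        roi_timeseries=ts,
        motion_fd=fd,
        motion_dvars=dvars,
        latent_covariance=latent_cov,
        tr_ms=tr_ms,
        scan_id=scan_id,
        subject_id=subject_id,
        timepoint=timepoint,
    )
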