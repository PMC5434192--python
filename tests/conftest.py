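"""Shared fixtures: small cohorts and null edge-data simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurolong.cohort import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(CohortParams(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic cohort: no noise, no jitter, no dropout."""
    params = CohortParams(
        beta=(2.0, 0.01, -0.02, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        sigma_b=0.0,
        sigma_e=0.0,
        time_jitter_sd=(0.0, 0.0, 0.0),
        retention_treatment=(1.0, 1.0, 1.0),
        retention_control=(1.0, 1.0, 1.0),
        seed=5,
    )
    cohort, truth = generate_cohort(params)
    return cohort, truth


def make_scan_design(
    n_per_group: int = 30,
    seed: int = 0,
    full_retention: bool = False,
) -> pd.DataFrame:
    """Per-scan design rows (subject/group/time/covariates/FD) for edge models."""
    kw = {}
    if full_retention:
        kw = {
            "retention_treatment": (1.0, 1.0, 1.0),
            "retention_control": (1.0, 1.0, 1.0),
        }
    cohort, _ = generate_cohort(
        CohortParams(n_treatment=n_per_group, n_control=n_per_group, seed=seed, **kw)
    )
    rng = np.random.default_rng(seed + 977)
    design = cohort[["subject", "group", "timepoint", "time", "age", "bdi"]].copy()
    design["fd"] = np.abs(rng.normal(0.15, 0.05, len(design)))
    return design


def simulate_null_edges(
    design: pd.DataFrame,
    n_roi: int,
    rng: np.random.Generator,
    group_time: float = 0.0,
    group_hinge: float = 0.0,
    effect_edge: tuple[int, int] | None = None,
    t_break: float = 9.0,
) -> np.ndarray:
    """Standardized-edge-like stack drawn from per-edge piecewise LMEs.

    All edges share small nuisance effects and zero group-by-time slopes
    except, optionally, one ``effect_edge`` given the requested slopes.
    Per-edge variance components are mildly heterogeneous, totalling about
    unit variance as standardization implies.
    """
    n = len(design)
    t = design["time"].to_numpy(float)
    S = design["group"].to_numpy(float)
    hinge = np.clip(t - t_break, 0.0, None)
    bdi_bar = design.groupby("subject")["bdi"].transform("mean").to_numpy(float)
    fd_bar = design.groupby("subject")["fd"].transform("mean").to_numpy(float)
    nuisance = (
        0.2 * S
        - 0.005 * (design["age"].to_numpy(float) - 40.0)
        - 0.01 * (bdi_bar - 18.0)
        + 0.01 * (design["bdi"].to_numpy(float) - bdi_bar)
        - 0.3 * (design["fd"].to_numpy(float) - fd_bar)
    )
    codes = pd.factorize(design["subject"])[0]
    n_sub = codes.max() + 1
    iu, ju = np.triu_indices(n_roi, k=1)
    m = iu.size
    sigma_b = rng.uniform(0.5, 0.7, m)
    sigma_e = rng.uniform(0.6, 0.8, m)
    slope = np.zeros(m)
    slope_change = np.zeros(m)
    if effect_edge is not None:
        k = np.flatnonzero((iu == effect_edge[0]) & (ju == effect_edge[1]))[0]
        slope[k] = group_time
        slope_change[k] = group_hinge
    mean = (
        nuisance[:, None]
        + (S * t)[:, None] * slope[None, :]
        + (S * hinge)[:, None] * slope_change[None, :]
    )
    b = rng.standard_normal((n_sub, m)) * sigma_b
    Y = mean + b[codes] + rng.standard_normal((n, m)) * sigma_e
    stack = np.zeros((n, n_roi, n_roi))
    stack[:, iu, ju] = Y
    stack[:, ju, iu] = Y
    return stack
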