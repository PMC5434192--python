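"""Scan-level functional connectivity: scrubbing, trimming, Fisher z.

The processing contract mirrors standard resting-state practice: frames are
censored ("scrubbed") when framewise displacement exceeds 0.5 mm or
standardized DVARS exceeds 1.8 (the DVARS cut can also be derived from the
pooled data as median + 1.5 IQR); scans keeping less than 4 minutes of data
fail QA; surviving scans are trimmed to the cohort-wide minimum frame count
so every correlation uses the same degrees of freedom; ROI-pair Pearson
correlations are Fisher z-transformed; and each edge is finally scaled to
zero mean / unit variance across all scans pooled, the form the downstream
longitudinal models consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import ScanSimulation

__all__ = [
    "QAError",
    "FrameMask",
    "ScanConnectivity",
    "scrub_frames",
    "derive_dvars_threshold",
    "apply_mask",
    "trim_to_common_length",
    "compute_connectivity",
    "EdgeStandardizer",
    "standardize_edges",
    "edge_table_from_stack",
]

FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 1.8
MIN_SECONDS = 240.0


class QAError(RuntimeError):
    """A scan failed a quality-assurance rule."""


@dataclass
class FrameMask:
    """Per-frame keep decisions for one scan."""

    keep: np.ndarray
    fd_threshold: float = FD_THRESHOLD_MM
    dvars_threshold: float = DVARS_THRESHOLD
    seconds_retained: float = 0.0
    passes_floor: bool = True

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class ScanConnectivity:
    """Symmetric Fisher-z connectivity for one scan plus provenance."""

    z_matrix: np.ndarray
    n_frames_used: int
    fd_mean_after: float
    scan_id: str = ""
    subject_id: str = ""
    timepoint: int = 0


def scrub_frames(
    scan: ScanSimulation,
    fd_threshold: float = FD_THRESHOLD_MM,
    dvars_threshold: float = DVARS_THRESHOLD,
    min_seconds: float = MIN_SECONDS,
) -> FrameMask:
    """Censor frames with FD or standardized DVARS above threshold.

    A frame survives iff ``FD <= fd_threshold`` and
    ``DVARS <= dvars_threshold``.  The mask records the retained duration
    and whether the scan clears the 4-minute reliability floor; a scan with
    no surviving frames is rejected outright.
    """
    keep = (np.asarray(scan.motion_fd) <= fd_threshold) & (
        np.asarray(scan.motion_dvars) <= dvars_threshold
    )
    if not keep.any():
        raise QAError(f"scan {scan.scan_id or '<unnamed>'}: all frames scrubbed")
    seconds = float(keep.sum() * scan.tr_ms / 1000.0)
    return FrameMask(
        keep=keep,
        fd_threshold=fd_threshold,
        dvars_threshold=dvars_threshold,
        seconds_retained=seconds,
        passes_floor=seconds >= min_seconds,
    )


def derive_dvars_threshold(dvars_all_scans) -> float:
    """Median + 1.5 IQR of standardized DVARS pooled over frames and runs."""
    values = np.asarray(dvars_all_scans, float).ravel()
    if values.size < 4:
        raise ValueError("need at least 4 pooled DVARS values to form quartiles")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med + 1.5 * (q3 - q1))


def apply_mask(scan: ScanSimulation, mask: FrameMask) -> np.ndarray:
    """Kept frames of a scan, in temporal order."""
    return scan.roi_timeseries[mask.keep]


def trim_to_common_length(
    kept_series: list[np.ndarray],
    subsample: str = "head",
    seed: int | None = None,
) -> list[np.ndarray]:
    """Truncate every kept-frame series to the cohort-wide minimum count.

    The default keeps the *earliest* surviving frames (temporal order), so
    the pipeline is deterministic without a seed; ``subsample="random"``
    draws a seeded random subset instead (kept in temporal order).
    """
    if not kept_series:
        raise ValueError("no scans to trim")
    if subsample not in ("head", "random"):
        raise ValueError("subsample must be 'head' or 'random'")
    k = min(ts.shape[0] for ts in kept_series)
    if subsample == "head":
        return [ts[:k] for ts in kept_series]
    rng = np.random.default_rng(seed)
    return [
        ts[np.sort(rng.choice(ts.shape[0], size=k, replace=False))]
        for ts in kept_series
    ]


def compute_connectivity(
    ts: np.ndarray,
    scan_id: str = "",
    subject_id: str = "",
    timepoint: int = 0,
    fd_mean_after: float = np.nan,
    cap_extreme: bool = False,
) -> ScanConnectivity:
    """Fisher-z connectivity matrix from trimmed ROI time series.

    ``z = atanh(r)`` elementwise off the diagonal (the diagonal is set to
    0 and excluded from every downstream statistic).  A perfectly
    correlated ROI pair signals degenerate input and raises, unless
    ``cap_extreme`` caps ``|r|`` at 1 - 1e-6.
    """
    ts = np.asarray(ts, float)
    if ts.ndim != 2 or ts.shape[0] < 2 or ts.shape[1] < 2:
        raise ValueError("need a frames x ROI matrix with >= 2 frames and >= 2 ROIs")
    sd = ts.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant time series for ROI index(es) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    extreme = off & (np.abs(r) >= 1.0 - 1e-12)
    if extreme.any():
        if not cap_extreme:
            i, j = np.argwhere(extreme)[0]
            raise ValueError(
                f"perfect correlation between ROIs {i} and {j}; "
                "degenerate input (pass cap_extreme=True to cap)"
            )
        r = np.clip(r, -(1 - 1e-6), 1 - 1e-6)
    z = np.arctanh(np.where(off, r, 0.0))
    z = (z + z.T) / 2.0
    return ScanConnectivity(
        z_matrix=z,
        n_frames_used=ts.shape[0],
        fd_mean_after=float(fd_mean_after),
        scan_id=scan_id,
        subject_id=subject_id,
        timepoint=timepoint,
    )


class EdgeStandardizer(BaseEstimator, TransformerMixin):
    """Per-edge zero-mean unit-variance scaling across a stack of scans.

    ``fit``/``transform`` act on an (n_scans, n_roi, n_roi) array of
    Fisher-z matrices; means and sample SDs are computed per off-diagonal
    edge over all scans pooled (both groups, all timepoints), which is the
    scaling applied before the longitudinal edge models.
    """

    def fit(self, X: np.ndarray, y=None) -> "EdgeStandardizer":
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[0] < 2:
            raise ValueError("need a stack of >= 2 scan matrices")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        off = ~np.eye(X.shape[1], dtype=bool)
        if np.any(self.scale_[off] == 0):
            i, j = np.argwhere(off & (self.scale_ == 0))[0]
            raise ValueError(f"edge ({i}, {j}) has zero variance across scans")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        off = ~np.eye(X.shape[1], dtype=bool)
        out = np.zeros_like(X)
        out[:, off] = (X[:, off] - self.mean_[off]) / self.scale_[off]
        return out


def standardize_edges(scans: list[ScanConnectivity]) -> tuple[np.ndarray, pd.DataFrame]:
    """Standardize a list of scan matrices; returns the stack and a long table."""
    stack = np.stack([s.z_matrix for s in scans])
    std_stack = EdgeStandardizer().fit_transform(stack)
    table = edge_table_from_stack(std_stack, scans, raw_stack=stack)
    return std_stack, table


def edge_table_from_stack(
    std_stack: np.ndarray,
    scans: list[ScanConnectivity],
    raw_stack: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format (scan, roi_i, roi_j, z, standardized z) edge table."""
    n_roi = std_stack.shape[1]
    iu, ju = np.triu_indices(n_roi, k=1)
    rows = []
    for k, scan in enumerate(scans):
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "subject": scan.subject_id,
                    "timepoint": scan.timepoint,
                    "roi_i": int(i),
                    "roi_j": int(j),
                    "z": float(raw_stack[k, i, j]) if raw_stack is not None else np.nan,
                    "z_std": float(std_stack[k, i, j]),
                }
            )
    return pd.DataFrame(rows)
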