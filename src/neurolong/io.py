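"""On-disk interchange: long-format TSV tables, scan matrices, manifests.

The canonical cohort format is one visit per row
(``subject group timepoint time age bdi <outcomes...>``), tab-separated.
Scans are frames-by-ROI delimited matrices with a companion motion TSV
(``frame fd dvars``); nested results (fits, network statistics) go to
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ScanSimulation

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_scan",
    "load_scan",
    "save_manifest",
    "load_manifest",
    "save_json",
]

REQUIRED_COHORT_COLUMNS = ("subject", "group", "timepoint", "time")


def save_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False)
    return path


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table lacks columns {sorted(missing)}")
    return df


def save_scan(scan: ScanSimulation, directory, stem: str) -> tuple[Path, Path]:
    """Write a scan as ``<stem>_timeseries.tsv`` + ``<stem>_motion.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ts_path = directory / f"{stem}_timeseries.tsv"
    motion_path = directory / f"{stem}_motion.tsv"
    np.savetxt(ts_path, scan.roi_timeseries, delimiter="\t")
    motion = pd.DataFrame(
        {
            "frame": np.arange(scan.n_frames),
            "fd": scan.motion_fd,
            "dvars": scan.motion_dvars,
        }
    )
    motion.to_csv(motion_path, sep="\t", index=False)
    return ts_path, motion_path


def load_scan(ts_path, motion_path, tr_ms: float = 2000.0, **ids) -> ScanSimulation:
    ts = np.loadtxt(ts_path, delimiter="\t")
    motion = pd.read_csv(motion_path, sep="\t")
    if len(motion) != ts.shape[0]:
        raise ValueError(
            f"{motion_path}: {len(motion)} motion rows for {ts.shape[0]} frames"
        )
    return ScanSimulation(
        roi_timeseries=ts,
        motion_fd=motion["fd"].to_numpy(float),
        motion_dvars=motion["dvars"].to_numpy(float),
        latent_covariance=np.eye(ts.shape[1]),
        tr_ms=tr_ms,
        **ids,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def save_json(payload, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path


def save_manifest(params, truth: dict, path) -> Path:
    """Record seed, generator parameters and generative truth for a dataset."""
    payload = {"params": params, "truth": truth}
    return save_json(payload, path)


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
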