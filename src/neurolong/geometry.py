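"""ROI bookkeeping: network affiliation counts and connection distances.

ROI metadata (name, MNI center, surface area, resting-state network
affiliation from the canonical seven-network parcellation) is supplied as
a table, not computed from atlas rasters; the table is the contract.
Connection distances are Euclidean norms between ROI centers in MNI mm.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "RoiMeta",
    "SEVEN_NETWORKS",
    "load_roi_metadata",
    "default_roi_metadata",
    "edge_distance",
    "count_by_network_pair",
    "edge_distances_by_network_pair",
]

SEVEN_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "salience",
    "limbic",
    "frontoparietal",
    "default",
)


@dataclass(frozen=True)
class RoiMeta:
    index: int
    name: str
    mni_center: tuple[float, float, float]
    surface_area: float
    network: str


def load_roi_metadata(path) -> pd.DataFrame:
    """Read an ROI metadata CSV (index, name, x, y, z, surface_area, network)."""
    df = pd.read_csv(path)
    required = {"index", "name", "x", "y", "z", "network"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"ROI metadata lacks columns: {sorted(missing)}")
    if df["index"].duplicated().any():
        raise ValueError("ROI indices must be unique")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("ROI coordinates must be finite")
    return df.sort_values("index").reset_index(drop=True)


def default_roi_metadata() -> pd.DataFrame:
    """Bundled 12-ROI metadata table (see ``data/roi_metadata_synthetic.csv``).

    Coordinates and areas follow the published ROI table of the motivating
    study; the network column is a constructed affiliation assignment (the
    original atlas overlap is not distributed), hence the ``synthetic``
    label on the file.
    """
    with resources.files("neurolong.data").joinpath(
        "roi_metadata_synthetic.csv"
    ).open() as fh:
        return load_roi_metadata(fh)


def _center(roi) -> np.ndarray:
    if isinstance(roi, RoiMeta):
        return np.asarray(roi.mni_center, float)
    return np.asarray([roi["x"], roi["y"], roi["z"]], float)


def _index(roi):
    if isinstance(roi, RoiMeta):
        return roi.index
    if "index" in roi:
        return roi["index"]
    return roi.name  # row taken from a frame indexed by ROI index


def edge_distance(roi_a, roi_b) -> float:
    """Euclidean distance (mm) between two ROI centers."""
    if _index(roi_a) == _index(roi_b):
        raise ValueError("distance between an ROI and itself is not an edge")
    return float(np.linalg.norm(_center(roi_a) - _center(roi_b)))


def _pair_key(net_a: str, net_b: str) -> str:
    if net_a == net_b:
        return f"within-{net_a}"
    a, b = sorted((net_a, net_b))
    return f"between-{a}-{b}"


def count_by_network_pair(edges, roi_meta: pd.DataFrame) -> dict[str, int]:
    """Tally edges by unordered network pair.

    ``edges`` is an iterable of (roi_index_i, roi_index_j) pairs referring
    to the ``index`` column of ``roi_meta``; keys are ``within-<net>`` or
    ``between-<net>-<net>`` (alphabetical), and the counts sum to the
    number of edges.
    """
    nets = roi_meta.set_index("index")["network"]
    counts: Counter[str] = Counter()
    for i, j in edges:
        if i not in nets.index or j not in nets.index:
            raise KeyError(f"unknown ROI index in edge ({i}, {j})")
        counts[_pair_key(nets[i], nets[j])] += 1
    return dict(counts)


def edge_distances_by_network_pair(
    edges, roi_meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-edge Euclidean distance annotated with its network-pair key."""
    meta = roi_meta.set_index("index")
    rows = []
    for i, j in edges:
        a, b = meta.loc[i], meta.loc[j]
        rows.append(
            {
                "roi_i": i,
                "roi_j": j,
                "distance_mm": float(
                    np.linalg.norm(
                        a[["x", "y", "z"]].to_numpy(float)
                        - b[["x", "y", "z"]].to_numpy(float)
                    )
                ),
                "pair": _pair_key(a["network"], b["network"]),
            }
        )
    return pd.DataFrame(rows)
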