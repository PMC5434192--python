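"""Longitudinal network-based statistics with a parametric-bootstrap null.

Each ROI-pair edge gets the same piecewise random-intercept model as the
thickness analysis (with framewise-displacement covariates added); a Wald Z
for the requested group-by-time contrast is computed per edge; edges with
``|Z|`` above threshold form a graph over ROI nodes whose connected
components are the candidate findings, sized by edge count.  Because
longitudinal data are not exchangeable, the familywise null distribution of
the maximal component size is estimated by a *parametric bootstrap* rather
than permutation: every edge's data are re-simulated from its fitted model
with all group-by-time coefficients set to zero (baseline group offset and
nuisance covariates retained, variance components at their fitted values,
the observed missingness pattern reproduced exactly), refitted, and
re-thresholded.  Component p-values use the add-one rule
``(1 + #{null >= size}) / (1 + B)``.

Edges are simulated independently under the null (per-edge models, no
cross-edge covariance); see the methods note for the resulting caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._engine import MultiOutcomeEngine, group_sizes_from_sorted
from .lme import ContrastSpec, build_contrast

logger = logging.getLogger("neurolong")

__all__ = [
    "EdgeTestField",
    "NbsResult",
    "NetworkBasedStatistic",
    "edgewise_lme",
    "components_from_field",
    "max_component_edges",
    "parametric_bootstrap_null",
    "nbs_report",
]

Z_THRESHOLD = 1.96


@dataclass
class EdgeTestField:
    """Symmetric edge-wise Wald-Z field for one contrast."""

    z_stats: np.ndarray
    contrast: ContrastSpec | None = None
    threshold: float = Z_THRESHOLD


@dataclass
class NbsResult:
    """Supra-threshold components with their bootstrap p-values."""

    components: list[set[tuple[int, int]]]
    observed_max_size: int
    null_max_sizes: np.ndarray
    p_per_component: list[float]
    B: int
    threshold: float = Z_THRESHOLD
    z_field: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "components": [sorted(map(list, c)) for c in self.components],
            "component_sizes": [len(c) for c in self.components],
            "p_per_component": self.p_per_component,
            "observed_max_size": self.observed_max_size,
            "B": self.B,
            "threshold": self.threshold,
        }


def _union_find_components(edges: list[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[tuple[int, int]]] = {}
    for i, j in edges:
        groups.setdefault(find(i), set()).add((i, j))
    return sorted(groups.values(), key=len, reverse=True)


def components_from_field(
    field: EdgeTestField | np.ndarray, threshold: float | None = None
) -> list[set[tuple[int, int]]]:
    """Connected components of the supra-threshold graph, as edge sets.

    Nodes are ROI indices; an edge enters the graph iff ``|Z| > threshold``
    (strict).  Components are returned largest first; component size is the
    number of edges.  Non-finite Z values never enter the graph.
    """
    if isinstance(field, EdgeTestField):
        z, thr = field.z_stats, field.threshold
    else:
        z, thr = np.asarray(field, float), Z_THRESHOLD
    if threshold is not None:
        thr = threshold
    iu, ju = np.triu_indices(z.shape[0], k=1)
    zz = z[iu, ju]
    sel = np.isfinite(zz) & (np.abs(zz) > thr)
    edges = [(int(i), int(j)) for i, j in zip(iu[sel], ju[sel])]
    return _union_find_components(edges)


def max_component_edges(components: list[set[tuple[int, int]]]) -> int:
    return max((len(c) for c in components), default=0)


def _edge_design(
    design: pd.DataFrame,
    subject_covariates: tuple[str, ...],
    longitudinal_covariates: tuple[str, ...],
    breakpoint: float | None,
):
    """Fixed-effect design shared by every edge model.

    ``design`` has one row per scan: subject, group, timepoint, time plus
    covariate columns.  Time-varying covariates are centered within
    subject; all covariates must be complete (scans lacking them should be
    excluded upstream, mirroring the QA rules).
    """
    required = {"subject", "group", "timepoint", "time"}
    required |= set(subject_covariates) | set(longitudinal_covariates)
    missing = required - set(design.columns)
    if missing:
        raise KeyError(f"design lacks columns: {sorted(missing)}")
    if design[sorted(required)].isna().any().any():
        raise ValueError("design covariates must be complete for every scan")
    d = design.reset_index(drop=True).copy()
    order = d.sort_values(["subject", "time"], kind="stable").index.to_numpy()
    d = d.loc[order].reset_index(drop=True)

    t = d["time"].to_numpy(float)
    tp = d["timepoint"].to_numpy()
    t_break = float(breakpoint) if breakpoint is not None else float(t[tp == 2].mean())
    t_bar = {1: 0.0, 2: t_break, 3: float(t[tp == 3].mean())}
    S = d["group"].to_numpy(float)
    hinge = np.clip(t - t_break, 0.0, None)
    cols = {
        "intercept": np.ones_like(t),
        "time": t,
        "hinge": hinge,
        "group": S,
        "group_time": S * t,
        "group_hinge": S * hinge,
    }
    for cov in subject_covariates:
        cols[cov] = d[cov].to_numpy(float)
    for cov in longitudinal_covariates:
        mean = d.groupby("subject")[cov].transform("mean").to_numpy(float)
        cols[f"{cov}_between"] = mean
        cols[f"{cov}_within"] = d[cov].to_numpy(float) - mean
    structural = {"intercept", "time", "hinge", "group", "group_time", "group_hinge"}
    for name in [k for k in cols if k not in structural]:
        if np.ptp(cols[name]) == 0.0:
            logger.info("dropping constant covariate column %s", name)
            del cols[name]
    X = np.column_stack(list(cols.values()))
    codes = pd.factorize(d["subject"], sort=False)[0]
    starts, sizes = group_sizes_from_sorted(codes)
    meta = SimpleNamespace(
        feature_names=list(cols.keys()), t_break=t_break, t_bar=t_bar,
        beta=None, beta_cov=None,
    )
    return X, starts, sizes, order, meta


class NetworkBasedStatistic(BaseEstimator):
    """NBS for longitudinal edge data, scikit-learn estimator style.

    Parameters
    ----------
    contrast_label, scope
        Which change hypothesis the edge-wise Z field tests (default the
        between-group monotonic contrast).
    threshold
        Edge-level ``|Z|`` cut (1.96, i.e. p < .05 per connection).
    n_bootstrap
        Null replicates ``B`` (study-scale default 10_000; use ~200 for
        test presets).
    pooled_variance
        Simulate every null edge with the across-edge mean variance
        components instead of per-edge values (speed option).
    max_nonconverged_frac
        Drop a bootstrap replicate when more than this fraction of its
        edge refits is degenerate (non-finite Z).

    Fitted attributes: ``z_field_``, ``components_``,
    ``observed_max_size_``, ``null_max_sizes_``, ``p_values_``,
    ``result_``.
    """

    def __init__(
        self,
        contrast_label: str = "monotonic",
        scope: str = "between",
        threshold: float = Z_THRESHOLD,
        n_bootstrap: int = 10_000,
        random_state: int | None = None,
        subject_covariates: tuple[str, ...] = ("age",),
        longitudinal_covariates: tuple[str, ...] = ("bdi", "fd"),
        breakpoint: float | None = None,
        pooled_variance: bool = False,
        max_nonconverged_frac: float = 0.01,
    ):
        self.contrast_label = contrast_label
        self.scope = scope
        self.threshold = threshold
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.subject_covariates = subject_covariates
        self.longitudinal_covariates = longitudinal_covariates
        self.breakpoint = breakpoint
        self.pooled_variance = pooled_variance
        self.max_nonconverged_frac = max_nonconverged_frac

    # ------------------------------------------------------------------
    def _prepare(self, edges: np.ndarray, design: pd.DataFrame):
        edges = np.asarray(edges, float)
        if edges.ndim != 3 or edges.shape[1] != edges.shape[2]:
            raise ValueError("edges must be (n_scans, n_roi, n_roi)")
        if edges.shape[0] != len(design):
            raise ValueError("edge stack and design row counts differ")
        X, starts, sizes, order, meta = _edge_design(
            design,
            tuple(self.subject_covariates),
            tuple(self.longitudinal_covariates),
            self.breakpoint,
        )
        n_roi = edges.shape[1]
        iu, ju = np.triu_indices(n_roi, k=1)
        Y = edges[order][:, iu, ju]
        valid = ~np.isnan(Y).any(axis=0)
        if (~valid).any():
            logger.info("%d edge(s) with missing scans dropped", int((~valid).sum()))
        if np.any(Y[:, valid].std(axis=0) == 0):
            bad = np.flatnonzero(valid)[Y[:, valid].std(axis=0) == 0]
            raise ValueError(
                f"constant edge values (zero residual variance) at edge "
                f"index(es) {bad.tolist()}"
            )
        engine = MultiOutcomeEngine(X, starts, sizes)
        spec = build_contrast(meta, self.contrast_label, self.scope)
        return engine, Y, valid, (iu, ju), n_roi, meta, spec

    def fit(self, edges: np.ndarray, design: pd.DataFrame) -> "NetworkBasedStatistic":
        engine, Y, valid, (iu, ju), n_roi, meta, spec = self._prepare(edges, design)
        fitres = engine.fit_many(Y[:, valid])
        _, _, z = engine.contrast_z(fitres, spec.weights)
        z_field = np.full((n_roi, n_roi), np.nan)
        z_field[iu[valid], ju[valid]] = z
        z_field[ju[valid], iu[valid]] = z
        np.fill_diagonal(z_field, 0.0)
        self.contrast_ = spec
        self.z_field_ = z_field
        self.field_ = EdgeTestField(z_field, spec, self.threshold)
        self.components_ = components_from_field(self.field_)
        self.observed_max_size_ = max_component_edges(self.components_)

        # --- parametric bootstrap under the global null -------------------
        beta0 = fitres["beta"].copy()
        for name in ("group_time", "group_hinge"):
            beta0[meta.feature_names.index(name)] = 0.0
        sigma_b = np.sqrt(fitres["sigma_b2"])
        sigma_e = np.sqrt(fitres["sigma_e2"])
        if self.pooled_variance:
            sigma_b = np.full_like(sigma_b, sigma_b.mean())
            sigma_e = np.full_like(sigma_e, sigma_e.mean())
        self.null_max_sizes_ = parametric_bootstrap_null(
            engine,
            beta0,
            sigma_b,
            sigma_e,
            spec.weights,
            B=self.n_bootstrap,
            threshold=self.threshold,
            seed=self.random_state,
            edge_index=(iu[valid], ju[valid]),
            n_roi=n_roi,
            max_nonconverged_frac=self.max_nonconverged_frac,
        )
        B = self.null_max_sizes_.size
        self.p_values_ = [
            float((1 + np.sum(self.null_max_sizes_ >= len(c))) / (1 + B))
            for c in self.components_
        ]
        self.result_ = NbsResult(
            components=self.components_,
            observed_max_size=self.observed_max_size_,
            null_max_sizes=self.null_max_sizes_,
            p_per_component=self.p_values_,
            B=B,
            threshold=self.threshold,
            z_field=z_field,
        )
        return self

    @property
    def significant_components_(self):
        return [
            c for c, p in zip(self.components_, self.p_values_) if p < 0.05
        ]


def parametric_bootstrap_null(
    engine: MultiOutcomeEngine,
    beta_null: np.ndarray,
    sigma_b: np.ndarray,
    sigma_e: np.ndarray,
    weights: np.ndarray,
    B: int,
    threshold: float = Z_THRESHOLD,
    seed: int | None = None,
    edge_index: tuple[np.ndarray, np.ndarray] | None = None,
    n_roi: int | None = None,
    max_nonconverged_frac: float = 0.01,
) -> np.ndarray:
    """Null distribution of the maximal supra-threshold component size.

    For each replicate, every edge's longitudinal data are drawn from its
    fitted model with the group-by-time coefficients zeroed, refitted on
    the identical design (hence the identical missingness), and the
    largest connected component of ``|Z| > threshold`` edges recorded.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    m = beta_null.shape[1]
    if edge_index is None:
        if n_roi is None:
            n_roi = int((1 + np.sqrt(1 + 8 * m)) / 2)
        edge_index = np.triu_indices(n_roi, k=1)
    iu, ju = edge_index
    sizes = np.empty(B, int)
    dropped = 0
    k = 0
    while k < B:
        Y = engine.simulate(beta_null, sigma_b, sigma_e, rng)
        fit = engine.fit_many(Y)
        _, _, z = engine.contrast_z(fit, weights)
        bad = ~np.isfinite(z)
        if bad.mean() > max_nonconverged_frac:
            dropped += 1
            if dropped > max(10, B // 10):
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        sel = np.isfinite(z) & (np.abs(z) > threshold)
        comps = _union_find_components(
            [(int(i), int(j)) for i, j in zip(iu[sel], ju[sel])]
        )
        sizes[k] = max_component_edges(comps)
        k += 1
    if dropped:
        logger.info("dropped %d degenerate bootstrap replicate(s)", dropped)
    return sizes


def edgewise_lme(
    edges: np.ndarray,
    design: pd.DataFrame,
    contrast_label: str = "monotonic",
    scope: str = "between",
    threshold: float = Z_THRESHOLD,
    subject_covariates: tuple[str, ...] = ("age",),
    longitudinal_covariates: tuple[str, ...] = ("bdi", "fd"),
    breakpoint: float | None = None,
) -> EdgeTestField:
    """Edge-wise piecewise-LME Wald-Z field for one contrast (no bootstrap)."""
    est = NetworkBasedStatistic(
        contrast_label=contrast_label,
        scope=scope,
        threshold=threshold,
        subject_covariates=subject_covariates,
        longitudinal_covariates=longitudinal_covariates,
        breakpoint=breakpoint,
    )
    engine, Y, valid, (iu, ju), n_roi, meta, spec = est._prepare(edges, design)
    fitres = engine.fit_many(Y[:, valid])
    _, _, z = engine.contrast_z(fitres, spec.weights)
    z_field = np.full((n_roi, n_roi), np.nan)
    z_field[iu[valid], ju[valid]] = z
    z_field[ju[valid], iu[valid]] = z
    np.fill_diagonal(z_field, 0.0)
    return EdgeTestField(z_field, spec, threshold)


def nbs_report(result: NbsResult, roi_meta: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-component table with ROI names and significance flags."""
    names = roi_meta["name"].tolist()
    rows = []
    for idx, (comp, p) in enumerate(
        zip(result.components, result.p_per_component), start=1
    ):
        for i, j in sorted(comp):
            if i >= len(names) or j >= len(names):
                raise IndexError(f"ROI index ({i}, {j}) outside metadata")
            rows.append(
                {
                    "component": idx,
                    "size": len(comp),
                    "p_nbs": p,
                    "significant": p < alpha,
                    "roi_i": i,
                    "roi_j": j,
                    "roi_i_name": names[i],
                    "roi_j_name": names[j],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "component", "size", "p_nbs", "significant",
            "roi_i", "roi_j", "roi_i_name", "roi_j_name",
        ],
    )
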