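"""Network statistics: component search, bootstrap null, p-value rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_scan_design, simulate_null_edges
from neurolong.geometry import default_roi_metadata
from neurolong.nbs import (
    NetworkBasedStatistic,
    NbsResult,
    components_from_field,
    edgewise_lme,
    max_component_edges,
    nbs_report,
)


def _field_from_edges(edges, n=8, z=3.0):
    f = np.zeros((n, n))
    for i, j in edges:
        f[i, j] = f[j, i] = z
    return f


def test_components_simple_graph():
    field = _field_from_edges([(1, 2), (2, 3), (5, 6)])
    comps = components_from_field(field)
    assert [set(c) for c in comps] == [{(1, 2), (2, 3)}, {(5, 6)}]
    assert max_component_edges(comps) == 2
    assert components_from_field(np.zeros((8, 8))) == []


def test_components_match_networkx_oracle():
    """Union-find partition equals graph reachability on random fields."""
    import networkx as nx

    rng = np.random.default_rng(0)
    for _ in range(300):
        z = rng.standard_normal((12, 12)) * 1.5
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        comps = components_from_field(z, threshold=1.96)
        G = nx.Graph()
        iu, ju = np.triu_indices(12, k=1)
        for i, j in zip(iu, ju):
            if abs(z[i, j]) > 1.96:
                G.add_edge(int(i), int(j))
        expected = {
            frozenset((min(a, b), max(a, b)) for a, b in G.subgraph(cc).edges)
            for cc in nx.connected_components(G)
        }
        assert {frozenset(c) for c in comps} == expected


def test_add_one_p_value_rule():
    null = np.r_[np.full(3, 10), np.zeros(9_996)]
    res = NbsResult(
        components=[{(0, 1)} | {(1, k) for k in range(2, 11)}],
        observed_max_size=10,
        null_max_sizes=null,
        p_per_component=[(1 + np.sum(null >= 10)) / (1 + null.size)],
        B=null.size,
    )
    assert res.p_per_component[0] == pytest.approx(0.0004)


def test_edgewise_field_null_level_and_power():
    """Edge-level |Z|>1.96 rate is ~5% under the null; a planted effect wins."""
    design = make_scan_design(n_per_group=30, seed=1)
    rng = np.random.default_rng(7)
    rates, argmax_hits = [], 0
    n_rounds = 25
    for k in range(n_rounds):
        stack = simulate_null_edges(design, 12, rng)
        field = edgewise_lme(stack, design)
        iu, ju = np.triu_indices(12, k=1)
        rates.append(np.mean(np.abs(field.z_stats[iu, ju]) > 1.96))
        planted = simulate_null_edges(
            design, 12, rng, group_time=0.12, effect_edge=(2, 9)
        )
        f2 = edgewise_lme(planted, design)
        argmax_hits += np.nanargmax(np.abs(f2.z_stats[iu, ju])) == int(
            np.flatnonzero((iu == 2) & (ju == 9))[0]
        )
    assert np.mean(rates) == pytest.approx(0.05, abs=0.02)
    assert argmax_hits >= int(0.9 * n_rounds)


def test_edgewise_rejects_constant_edge():
    design = make_scan_design(n_per_group=10, seed=2)
    stack = simulate_null_edges(design, 4, np.random.default_rng(0))
    stack[:, 0, 1] = stack[:, 1, 0] = 1.0
    with pytest.raises(ValueError, match="constant edge"):
        edgewise_lme(stack, design)


def test_nbs_fit_determinism_and_pvalues():
    design = make_scan_design(n_per_group=15, seed=3)
    stack = simulate_null_edges(
        design, 6, np.random.default_rng(5), group_time=0.15, effect_edge=(0, 1)
    )

    def run():
        return NetworkBasedStatistic(n_bootstrap=99, random_state=7).fit(
            stack, design
        )

    a, b = run(), run()
    assert np.array_equal(a.null_max_sizes_, b.null_max_sizes_)
    assert a.p_values_ == b.p_values_
    assert np.allclose(a.z_field_, b.z_field_, equal_nan=True)
    for c, p in zip(a.components_, a.p_values_):
        assert 0 < p <= 1
        # tail-count p is monotone nonincreasing in component size
    sizes = [len(c) for c in a.components_]
    order = np.argsort(sizes)[::-1]
    ps = np.array(a.p_values_)[order]
    assert np.all(np.diff(ps) >= 0)
    assert a.observed_max_size_ == max(sizes, default=0)
    with pytest.raises(ValueError, match="bootstrap"):
        NetworkBasedStatistic(n_bootstrap=0).fit(stack, design)
    pooled = NetworkBasedStatistic(
        n_bootstrap=99, random_state=7, pooled_variance=True
    ).fit(stack, design)
    assert pooled.observed_max_size_ == a.observed_max_size_


def test_nbs_roi_relabel_invariance():
    """Permuting ROI labels leaves the max-component bootstrap p unchanged."""
    design = make_scan_design(n_per_group=15, seed=4)
    stack = simulate_null_edges(
        design, 6, np.random.default_rng(9), group_time=0.15, effect_edge=(1, 4)
    )
    perm = np.array([3, 0, 5, 1, 4, 2])
    permuted = stack[:, perm][:, :, perm]
    a = NetworkBasedStatistic(n_bootstrap=400, random_state=11).fit(stack, design)
    b = NetworkBasedStatistic(n_bootstrap=400, random_state=11).fit(permuted, design)
    # the observed field is exactly equivariant under the relabeling
    assert np.allclose(
        a.z_field_[perm][:, perm], b.z_field_, atol=1e-10, equal_nan=True
    )
    assert a.observed_max_size_ == b.observed_max_size_
    # the bootstrap consumes draws in edge order, so the null is invariant in
    # distribution only: compare within Monte-Carlo error
    pa = min(a.p_values_) if a.p_values_ else 1.0
    pb = min(b.p_values_) if b.p_values_ else 1.0
    assert pa == pytest.approx(pb, abs=0.1)


def test_null_max_size_grows_with_edge_count():
    """More independent edges stochastically inflate the max component size."""
    rng = np.random.default_rng(13)
    means = []
    for n_roi in (6, 12):
        iu, ju = np.triu_indices(n_roi, k=1)
        sizes = []
        for _ in range(400):
            z = rng.standard_normal(iu.size)
            sel = np.abs(z) > 1.96
            field = np.zeros((n_roi, n_roi))
            field[iu[sel], ju[sel]] = 3.0
            field[ju[sel], iu[sel]] = 3.0
            sizes.append(max_component_edges(components_from_field(field)))
        means.append(np.mean(sizes))
    assert means[1] > means[0]


def test_nbs_report_table():
    roi_meta = default_roi_metadata()
    empty = NbsResult([], 0, np.zeros(10), [], 10)
    assert nbs_report(empty, roi_meta).empty
    res = NbsResult(
        components=[{(0, 1), (1, 2)}],
        observed_max_size=2,
        null_max_sizes=np.full(50, 5),
        p_per_component=[1.0],
        B=50,
    )
    table = nbs_report(res, roi_meta)
    assert table["p_nbs"].iloc[0] == 1.0  # null always >= size -> p = 1
    assert not table["significant"].any()
    assert set(table["roi_i_name"]) <= set(roi_meta["name"])
    bad = NbsResult([{(0, 40)}], 1, np.zeros(5), [0.5], 5)
    with pytest.raises(IndexError):
        nbs_report(bad, roi_meta)
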