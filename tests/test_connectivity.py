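"""Scrubbing, trimming, Fisher-z and edge standardization rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurolong.cohort import ScanSimulation, SpikeParams, generate_scan
from neurolong.connectivity import (
    EdgeStandardizer,
    QAError,
    apply_mask,
    compute_connectivity,
    derive_dvars_threshold,
    scrub_frames,
    standardize_edges,
    trim_to_common_length,
)


def _scan(fd, dvars, n_roi=3, tr_ms=2000.0, seed=0):
    fd = np.asarray(fd, float)
    rng = np.random.default_rng(seed)
    return ScanSimulation(
        roi_timeseries=rng.standard_normal((fd.size, n_roi)),
        motion_fd=fd,
        motion_dvars=np.asarray(dvars, float),
        latent_covariance=np.eye(n_roi),
        tr_ms=tr_ms,
        scan_id="s",
    )


def test_scrub_rule_application():
    """Frame kept iff FD <= 0.5 AND DVARS <= 1.8."""
    mask = scrub_frames(_scan([0.1, 0.6, 0.2], [1.0, 1.0, 2.0]))
    assert mask.keep.tolist() == [True, False, False]
    assert mask.n_kept == 1
    all_kept = scrub_frames(
        _scan([0.1, 0.6, 0.2], [1.0, 1.0, 2.0]), np.inf, np.inf
    )
    assert all_kept.keep.all()


def test_scrub_four_minute_floor():
    """90 kept frames at TR 2 s is 180 s: below the 240 s reliability floor."""
    fd = np.r_[np.full(90, 0.1), np.full(118, 0.9)]
    dvars = np.ones(208)
    mask = scrub_frames(_scan(fd, dvars))
    assert mask.n_kept == 90
    assert mask.seconds_retained == pytest.approx(180.0)
    assert not mask.passes_floor
    with pytest.raises(QAError, match="scrubbed"):
        scrub_frames(_scan([0.9, 0.9], [1.0, 1.0]))


def test_dvars_threshold_rule():
    assert derive_dvars_threshold([1, 2, 3, 4, 5]) == pytest.approx(6.0)
    assert derive_dvars_threshold([2.2] * 10) == pytest.approx(2.2)
    rng = np.random.default_rng(0)
    pooled = rng.normal(1.0, 0.3, 200_000)
    assert derive_dvars_threshold(pooled) == pytest.approx(1.607, abs=0.03)
    with pytest.raises(ValueError, match="4"):
        derive_dvars_threshold([1.0, 2.0, 3.0])


def test_trim_to_common_length_keeps_earliest():
    rng = np.random.default_rng(1)
    series = [rng.standard_normal((n, 2)) for n in (121, 150, 130)]
    trimmed = trim_to_common_length(series)
    assert all(t.shape[0] == 121 for t in trimmed)
    # order-preserving oracle: output is exactly the first k rows
    for orig, t in zip(series, trimmed):
        assert np.array_equal(t, orig[:121])
    single = trim_to_common_length([series[0]])
    assert np.array_equal(single[0], series[0])
    with pytest.raises(ValueError):
        trim_to_common_length([])


def test_trim_random_subsample_mode():
    rng = np.random.default_rng(4)
    series = [rng.standard_normal((n, 2)) for n in (30, 45)]
    a = trim_to_common_length(series, subsample="random", seed=5)
    b = trim_to_common_length(series, subsample="random", seed=5)
    assert all(x.shape[0] == 30 for x in a)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    # temporal order preserved: rows appear in original order
    rows = [np.flatnonzero((series[1] == r).all(axis=1))[0] for r in a[1]]
    assert np.all(np.diff(rows) > 0)
    with pytest.raises(ValueError, match="subsample"):
        trim_to_common_length(series, subsample="shuffle")


def test_fisher_z_values():
    rng = np.random.default_rng(2)
    base = rng.standard_normal(4000)
    # construct a pair with r ~ 0.5 and check z = atanh(r)
    other = 0.5 * base + np.sqrt(1 - 0.25) * rng.standard_normal(4000)
    third = rng.standard_normal(4000)
    conn = compute_connectivity(np.column_stack([base, other, third]))
    r = np.corrcoef(base, other)[0, 1]
    assert conn.z_matrix[0, 1] == pytest.approx(np.arctanh(r), abs=1e-12)
    assert np.allclose(conn.z_matrix, conn.z_matrix.T)
    assert np.all(np.diag(conn.z_matrix) == 0)
    assert np.arctanh(0.5) == pytest.approx(0.5493, abs=5e-5)


def test_perfect_correlation_policy():
    x = np.arange(50.0)
    ts = np.column_stack([x, x * 2.0 + 1.0, np.sin(x)])
    with pytest.raises(ValueError, match="perfect correlation"):
        compute_connectivity(ts)
    capped = compute_connectivity(ts, cap_extreme=True)
    assert np.isfinite(capped.z_matrix).all()
    with pytest.raises(ValueError, match="constant"):
        compute_connectivity(np.column_stack([x, np.ones(50)]))


def test_edge_standardization_moments():
    rng = np.random.default_rng(3)
    stack = rng.standard_normal((7, 4, 4)) * 0.4 + 1.0
    stack = (stack + stack.transpose(0, 2, 1)) / 2
    for k in range(7):
        np.fill_diagonal(stack[k], 0.0)
    out = EdgeStandardizer().fit_transform(stack)
    off = ~np.eye(4, dtype=bool)
    assert np.all(np.abs(out[:, off].mean(axis=0)) < 1e-10)
    assert np.allclose(out[:, off].std(axis=0, ddof=1), 1.0)
    # two scans: values become -+1/sqrt(2) with order preserved
    two = stack[:2]
    z2 = EdgeStandardizer().fit_transform(two)
    ordered = np.sign(two[1] - two[0])[off]
    assert np.allclose(z2[1][off], ordered / np.sqrt(2))


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_standardization_is_monotone_per_edge(seed):
    """Standardization never reorders scans within an edge."""
    rng = np.random.default_rng(seed)
    stack = rng.standard_normal((5, 3, 3))
    stack = (stack + stack.transpose(0, 2, 1)) / 2
    out = EdgeStandardizer().fit_transform(stack)
    iu, ju = np.triu_indices(3, k=1)
    for i, j in zip(iu, ju):
        assert np.array_equal(
            np.argsort(stack[:, i, j]), np.argsort(out[:, i, j])
        )


def test_pipeline_determinism_and_block_structure():
    """Identical inputs give identical matrices; blocks survive the pipeline."""
    R = np.full((4, 4), 0.05)
    R[:2, :2] = R[2:, 2:] = 0.6
    np.fill_diagonal(R, 1.0)
    scans = [
        generate_scan(R, 400, SpikeParams(rate=0.1), seed=s, scan_id=f"s{s}")
        for s in range(6)
    ]
    def run():
        kept = [apply_mask(s, scrub_frames(s)) for s in scans]
        conns = [
            compute_connectivity(ts, scan_id=s.scan_id)
            for ts, s in zip(trim_to_common_length(kept), scans)
        ]
        return standardize_edges(conns)

    stack1, table1 = run()
    stack2, table2 = run()
    assert np.array_equal(stack1, stack2)
    assert table1.equals(table2)
    raw = np.stack(
        [
            compute_connectivity(apply_mask(s, scrub_frames(s))).z_matrix
            for s in scans
        ]
    )
    within = raw[:, [0, 2], [1, 3]].mean()
    between = raw[:, [0, 0, 1, 1], [2, 3, 2, 3]].mean()
    assert within > between
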