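"""Piecewise mixed model: oracles, contrast algebra, Wald calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurolong._engine import (
    MultiOutcomeEngine,
    ProfilePieces,
    SingularDesignError,
    _profile_eval,
    fit_random_intercept_ml,
    group_sizes_from_sorted,
)
from neurolong.cohort import CohortParams, generate_cohort
from neurolong.lme import (
    PiecewiseLME,
    build_contrast,
    center_covariate,
    fit_piecewise_lme,
)
from neurolong.lme import test_contrast as wald_test


def _fake_fit(t_break, t_bar3):
    """Minimal object carrying what contrast construction needs."""
    from types import SimpleNamespace

    names = ["intercept", "time", "hinge", "group", "group_time", "group_hinge"]
    return SimpleNamespace(
        feature_names=names,
        t_break=t_break,
        t_bar={1: 0.0, 2: t_break, 3: t_bar3},
        beta=np.zeros(6),
        beta_cov=np.eye(6),
    )


# ---------------------------------------------------------------------------
# estimation oracles


def test_gls_profile_oracle():
    """At fixed variance ratio, beta equals direct GLS with the block covariance."""
    rng = np.random.default_rng(0)
    sizes = np.array([3, 2, 4, 3])
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    n = sizes.sum()
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = rng.standard_normal(n)
    pieces = ProfilePieces(X, starts, sizes)
    Xty, Gy, yty = X.T @ y, np.add.reduceat(y, starts), float(y @ y)
    for lam in (0.0, 0.3, 2.0, 50.0):
        _, beta, _, _ = _profile_eval(pieces, lam, Xty, Gy, yty)
        V = np.zeros((n, n))
        for s, m in zip(starts, sizes):
            V[s : s + m, s : s + m] = np.eye(m) + lam
        beta_gls = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, y))
        assert np.allclose(beta, beta_gls, atol=1e-10)


def test_matches_statsmodels_mixedlm(default_cohort):
    """Full ML fit agrees with an independent mixed-model implementation."""
    import statsmodels.formula.api as smf

    cohort, _ = default_cohort
    est = PiecewiseLME(outcome="thickness").fit(cohort)
    d = est.data_.copy()
    d["hinge"] = np.clip(d["time"] - est.t_break_, 0, None)
    mf = smf.mixedlm(
        "thickness ~ time + hinge + group + group:time + group:hinge"
        " + age + bdi_between + bdi_within",
        d,
        groups=d["subject"],
    ).fit(reml=False)
    assert est.loglik_ == pytest.approx(mf.llf, abs=1e-5)
    sm_beta = [
        mf.params[k]
        for k in ("Intercept", "time", "hinge", "group", "group:time",
                  "group:hinge", "age", "bdi_between", "bdi_within")
    ]
    assert np.allclose(est.beta_, sm_beta, atol=1e-6)
    assert est.sigma_e2_ == pytest.approx(mf.scale, rel=1e-3)
    assert est.sigma_b2_ == pytest.approx(float(mf.cov_re.iloc[0, 0]), rel=1e-3)


def test_singleton_subjects_clamp_to_ols():
    """No repeated measures: sigma_b^2 hits the boundary (warned) and beta = OLS."""
    rng = np.random.default_rng(4)
    n = 120
    d = pd.DataFrame(
        {
            "subject": [f"P{i}" for i in range(n)],
            "group": np.r_[np.ones(n // 2), np.zeros(n // 2)],
            "timepoint": np.tile([1, 2, 3], n)[:n],
            "time": np.tile([0.0, 9.0, 21.0], n)[:n],
            "age": rng.normal(40, 10, n),
            "bdi": rng.uniform(0, 30, n),
        }
    )
    d["y"] = rng.standard_normal(n) + 0.01 * d["time"]
    # singleton subjects leave the within-subject BDI column identically zero,
    # so the model drops the longitudinal covariate entirely
    with pytest.warns(RuntimeWarning, match="boundary"):
        est = PiecewiseLME(outcome="y", longitudinal_covariates=()).fit(d)
    assert est.sigma_b2_ == 0.0
    X = np.column_stack(
        [
            np.ones(n),
            est.data_["time"],
            np.clip(est.data_["time"] - est.t_break_, 0, None),
            est.data_["group"],
            est.data_["group"] * est.data_["time"],
            est.data_["group"] * np.clip(est.data_["time"] - est.t_break_, 0, None),
            est.data_["age"],
        ]
    )
    ols, *_ = np.linalg.lstsq(X, est.data_["y"], rcond=None)
    assert np.allclose(est.beta_, ols, rtol=1e-8, atol=1e-10)


def test_single_group_is_singular(default_cohort):
    cohort, _ = default_cohort
    one_arm = cohort[cohort["group"] == 1]
    with pytest.raises(SingularDesignError):
        PiecewiseLME(outcome="thickness").fit(one_arm)


def test_vectorised_grid_fit_matches_scalar(default_cohort):
    """The multi-outcome grid path reproduces the scalar Brent-search fit."""
    cohort, _ = default_cohort
    est = PiecewiseLME(outcome="thickness").fit(cohort)
    d = est.data_
    X = np.column_stack(
        [
            np.ones(len(d)), d["time"], np.clip(d["time"] - est.t_break_, 0, None),
            d["group"], d["group"] * d["time"],
            d["group"] * np.clip(d["time"] - est.t_break_, 0, None),
            d["age"], d["bdi_between"], d["bdi_within"],
        ]
    )
    codes = pd.factorize(d["subject"])[0]
    starts, sizes = group_sizes_from_sorted(codes)
    engine = MultiOutcomeEngine(X, starts, sizes)
    multi = engine.fit_many(d["thickness"].to_numpy()[:, None])
    assert np.allclose(multi["beta"][:, 0], est.beta_, rtol=5e-3, atol=5e-4)
    # grid discretisation costs a little likelihood but not inference
    assert multi["loglik"][0] == pytest.approx(est.loglik_, abs=0.5)
    assert multi["sigma_e2"][0] == pytest.approx(est.sigma_e2_, rel=0.1)
    w = build_contrast(est, "monotonic", "between").weights
    _, _, z_grid = engine.contrast_z(multi, w)
    z_scalar = wald_test(est, build_contrast(est, "monotonic", "between")).z
    assert z_grid[0] == pytest.approx(z_scalar, abs=0.05)


def test_time_shift_invariance(default_cohort):
    """Shifting all times and the breakpoint together leaves contrasts alone."""
    cohort, _ = default_cohort
    base = PiecewiseLME(outcome="thickness").fit(cohort)
    shifted = cohort.copy()
    shifted["time"] = shifted["time"] + 7.0
    moved = PiecewiseLME(outcome="thickness", breakpoint=base.t_break_ + 7.0).fit(
        shifted
    )
    moved.result_.t_bar = {k: v + 7.0 for k, v in base.t_bar_.items()}
    moved.result_.t_bar[1] = 7.0  # baseline average moved with the shift
    for scope in ("between", "within_treatment"):
        w0 = build_contrast(base, "monotonic", scope)
        r0 = wald_test(base, w0)
        # rebuild weights with shifted segment lengths: they are identical
        d1 = moved.result_.t_break - moved.result_.t_bar[1]
        d2 = moved.result_.t_bar[3] - moved.result_.t_break
        assert d1 == pytest.approx(base.t_break_ - 0.0, abs=1e-9)
        assert d2 == pytest.approx(base.t_bar_[3] - base.t_break_, abs=1e-9)
        r1 = wald_test(moved, w0)
        assert r1.z == pytest.approx(r0.z, rel=1e-6)


# ---------------------------------------------------------------------------
# covariate centering


def test_center_covariate_arithmetic():
    d = pd.DataFrame(
        {
            "subject": ["a", "a", "a", "b"],
            "bdi": [20.0, 15.0, 10.0, 7.0],
        }
    )
    out = center_covariate(d, "bdi")
    assert list(out["bdi_between"]) == [15.0, 15.0, 15.0, 7.0]
    assert list(out["bdi_within"]) == [5.0, 0.0, -5.0, 0.0]


def test_center_covariate_missing_excluded(default_cohort):
    cohort, _ = default_cohort
    d = cohort.copy()
    d.loc[d.index[3], "bdi"] = np.nan
    out = center_covariate(d, "bdi")
    assert len(out) == len(d) - 1
    # within-parts orthogonal to subject indicators: per-subject sums vanish
    sums = out.groupby("subject")["bdi_within"].sum()
    assert np.allclose(sums, 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# contrast algebra


def test_contrast_weights_at_study_times():
    """At breakpoint 9 and final average 21: monotonic between = 21*b5 + 12*b6."""
    fit = _fake_fit(9.0, 21.0)
    mono = build_contrast(fit, "monotonic", "between")
    w = dict(zip(mono.feature_names, mono.weights))
    assert w["group_time"] == pytest.approx(21.0)
    assert w["group_hinge"] == pytest.approx(12.0)
    assert all(v == 0 for k, v in w.items() if k not in ("group_time", "group_hinge"))
    nonmono = build_contrast(fit, "nonmonotonic", "between")
    wn = dict(zip(nonmono.feature_names, nonmono.weights))
    assert wn["group_time"] == pytest.approx(-3.0)  # 9 - 12
    assert wn["group_hinge"] == pytest.approx(-12.0)
    ctrl = build_contrast(fit, "tp3_minus_tp2", "within_control")
    wc = dict(zip(ctrl.feature_names, ctrl.weights))
    assert wc["time"] == pytest.approx(12.0) and wc["hinge"] == pytest.approx(12.0)
    assert wc["group_time"] == 0.0


@settings(deadline=None, max_examples=50)
@given(
    t_break=st.floats(1.0, 15.0),
    gap=st.floats(0.5, 20.0),
    scope=st.sampled_from(["within_control", "within_treatment", "between"]),
)
def test_contrast_additivity(t_break, gap, scope):
    """monotonic = tp2_minus_tp1 + tp3_minus_tp2 for any times, exactly."""
    fit = _fake_fit(t_break, t_break + gap)
    w_mono = build_contrast(fit, "monotonic", scope).weights
    w_12 = build_contrast(fit, "tp2_minus_tp1", scope).weights
    w_23 = build_contrast(fit, "tp3_minus_tp2", scope).weights
    w_nm = build_contrast(fit, "nonmonotonic", scope).weights
    assert np.array_equal(w_mono, w_12 + w_23)
    assert np.array_equal(w_nm, w_12 - w_23)


def test_contrast_errors():
    fit = _fake_fit(9.0, 21.0)
    with pytest.raises(ValueError, match="label"):
        build_contrast(fit, "cubic", "between")
    with pytest.raises(ValueError, match="scope"):
        build_contrast(fit, "monotonic", "everyone")
    with pytest.raises(ValueError, match="degenerate"):
        wald_test(fit, np.zeros(6))


def test_wald_null_calibration():
    """Between-monotonic contrast rejects ~5% of null datasets at alpha=.05."""
    cohort, _ = generate_cohort(
        CohortParams(
            n_treatment=30, n_control=30,
            beta=(2.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            seed=99,
        )
    )
    est = PiecewiseLME(outcome="thickness").fit(cohort)
    d = est.data_
    X = np.column_stack(
        [
            np.ones(len(d)), d["time"], np.clip(d["time"] - est.t_break_, 0, None),
            d["group"], d["group"] * d["time"],
            d["group"] * np.clip(d["time"] - est.t_break_, 0, None),
            d["age"], d["bdi_between"], d["bdi_within"],
        ]
    )
    codes = pd.factorize(d["subject"])[0]
    starts, sizes = group_sizes_from_sorted(codes)
    engine = MultiOutcomeEngine(X, starts, sizes)
    n_seeds = 400
    rng = np.random.default_rng(2024)
    beta0 = np.zeros((9, n_seeds))
    beta0[0] = 2.5
    Y = engine.simulate(beta0, 0.12, 0.05, rng)
    fits = engine.fit_many(Y)
    w = build_contrast(est, "monotonic", "between").weights
    _, _, z = engine.contrast_z(fits, w)
    rate = np.mean(np.abs(z) > 1.96)
    assert rate == pytest.approx(0.05, abs=0.035)


def test_cov_shrinks_with_n():
    """Cov(beta) scales roughly like 1/n across cohort sizes."""
    ses = []
    for n in (40, 160):
        cohort, _ = generate_cohort(
            CohortParams(n_treatment=n, n_control=n, seed=12)
        )
        fit = fit_piecewise_lme(cohort, "thickness")
        ses.append(fit.se[fit.feature_names.index("group_time")])
    ratio = (ses[0] / ses[1]) ** 2
    assert 2.5 < ratio < 6.5  # ~4 expected for a 4x larger cohort
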