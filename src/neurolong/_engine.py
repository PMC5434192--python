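"""Profiled maximum-likelihood engine for the random-intercept model.

The marginal model is ``y = X beta + Z b + e`` with one random intercept per
subject, ``b ~ N(0, sigma_b^2)`` and ``e ~ N(0, sigma_e^2)``.  Writing
``lam = sigma_b^2 / sigma_e^2``, the per-subject marginal covariance is
``sigma_e^2 (I + lam J)`` whose inverse is available in closed form
(Sherman-Morrison), so for fixed ``lam`` both ``beta`` and ``sigma_e^2``
have closed-form ML solutions.  Estimation therefore reduces to a bounded
one-dimensional search over ``log(lam)``, which makes the boundary case
``sigma_b^2 = 0`` reachable exactly.

Two code paths share the same algebra:

* :func:`fit_random_intercept_ml` -- precise scalar fit (Brent search on
  ``log lam``) used for user-facing model fits;
* :class:`MultiOutcomeEngine` -- a vectorised fixed-grid fit over many
  outcome columns sharing one design, used by the edge-wise network
  statistics and its parametric bootstrap where tens of thousands of refits
  are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_LOG_2PI = np.log(2.0 * np.pi)

# lam below this is treated as the sigma_b^2 = 0 boundary
_BOUNDARY_LAM = 1e-8


class SingularDesignError(ValueError):
    """Raised when the fixed-effect design matrix is rank deficient."""


def group_sizes_from_sorted(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets and block sizes for a sorted integer group-code vector."""
    codes = np.asarray(codes)
    if codes.ndim != 1:
        raise ValueError("group codes must be one-dimensional")
    if np.any(np.diff(codes) < 0):
        raise ValueError("group codes must be sorted")
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    sizes = np.diff(np.r_[starts, codes.size])
    return starts, sizes


@dataclass
class ProfilePieces:
    """Sufficient statistics for the profiled likelihood of one (X, y)."""

    X: np.ndarray
    starts: np.ndarray
    sizes: np.ndarray
    XtX: np.ndarray = field(init=False)
    GX: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.XtX = self.X.T @ self.X
        self.GX = np.add.reduceat(self.X, self.starts, axis=0)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def whitened_normal_eq(self, lam: float, Xty: np.ndarray, Gy: np.ndarray):
        c = lam / (1.0 + lam * self.sizes)
        XWX = self.XtX - self.GX.T @ (c[:, None] * self.GX)
        XWy = Xty - self.GX.T @ (c * Gy)
        return XWX, XWy, c


def _profile_eval(pieces: ProfilePieces, lam: float, Xty, Gy, yty):
    """Profiled quantities at a fixed variance ratio lam."""
    n = pieces.n_obs
    XWX, XWy, c = pieces.whitened_normal_eq(lam, Xty, Gy)
    try:
        beta = linalg.solve(XWX, XWy, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularDesignError(str(exc)) from exc
    ywy = yty - c @ (Gy**2)
    rss = ywy - beta @ XWy
    rss = max(float(rss), 0.0)
    sigma_e2 = rss / n
    if sigma_e2 <= 0.0:
        raise ZeroDivisionError("zero residual variance (degenerate outcome)")
    loglik = -0.5 * (
        n * (_LOG_2PI + np.log(sigma_e2)) + np.sum(np.log1p(lam * pieces.sizes)) + n
    )
    return float(loglik), beta, sigma_e2, XWX


def fit_random_intercept_ml(
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    *,
    log_lam_bounds: tuple[float, float] = (-14.0, 10.0),
    xtol: float = 1e-10,
) -> dict:
    """Maximum-likelihood fit of the random-intercept model.

    ``X``/``y`` must be ordered so that each subject's rows are contiguous;
    ``starts``/``sizes`` describe the blocks.  Returns a dict with ``beta``,
    ``beta_cov``, ``sigma_b2``, ``sigma_e2``, ``loglik``, ``boundary``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "fixed-effect design matrix is rank deficient "
            f"(rank {np.linalg.matrix_rank(X)} < {X.shape[1]} columns)"
        )
    pieces = ProfilePieces(X, starts, sizes)
    Xty = X.T @ y
    Gy = np.add.reduceat(y, starts)
    yty = float(y @ y)

    def neg_pll(log_lam: float) -> float:
        ll, *_ = _profile_eval(pieces, np.exp(log_lam), Xty, Gy, yty)
        return -ll

    res = optimize.minimize_scalar(
        neg_pll, bounds=log_lam_bounds, method="bounded", options={"xatol": xtol}
    )
    lam_hat = float(np.exp(res.x))
    ll_hat = -float(res.fun)
    ll_zero, *_ = _profile_eval(pieces, 0.0, Xty, Gy, yty)
    boundary = False
    if ll_zero >= ll_hat - 1e-9 or lam_hat <= np.exp(log_lam_bounds[0] + 1e-6):
        lam_hat = 0.0
        boundary = True
    loglik, beta, sigma_e2, XWX = _profile_eval(pieces, lam_hat, Xty, Gy, yty)
    beta_cov = sigma_e2 * linalg.inv(XWX)
    if boundary:
        warnings.warn(
            "random-intercept variance estimated at the boundary "
            "(sigma_b^2 clamped to 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return {
        "beta": beta,
        "beta_cov": beta_cov,
        "sigma_b2": lam_hat * sigma_e2,
        "sigma_e2": sigma_e2,
        "lam": lam_hat,
        "loglik": loglik,
        "boundary": boundary,
        "n_obs": pieces.n_obs,
        "n_groups": sizes.size,
    }


def default_lam_grid(n_points: int = 49) -> np.ndarray:
    """Variance-ratio grid including the sigma_b^2 = 0 boundary."""
    return np.r_[0.0, np.geomspace(1e-4, 1e4, n_points)]


class MultiOutcomeEngine:
    """Vectorised profiled-ML fits for many outcomes sharing one design.

    The design (X, subject blocks) is fixed at construction; per-``lam``
    factorisations are precomputed once, so each call to :meth:`fit_many`
    costs a handful of small matrix products per grid point.  The grid fit
    is what both the observed edge-wise statistics and every bootstrap
    refit use, keeping the two exactly comparable.
    """

    def __init__(
        self,
        X: np.ndarray,
        starts: np.ndarray,
        sizes: np.ndarray,
        lam_grid: np.ndarray | None = None,
    ):
        X = np.asarray(X, float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("fixed-effect design matrix is rank deficient")
        self.X = X
        self.starts = np.asarray(starts)
        self.sizes = np.asarray(sizes)
        self.n_obs, self.n_params = X.shape
        self.lam_grid = default_lam_grid() if lam_grid is None else np.asarray(lam_grid)
        self.GX = np.add.reduceat(X, self.starts, axis=0)
        XtX = X.T @ X
        self._A = []  # (p, g) per lam: GX' diag(c)
        self._c = []
        self._cho = []
        self._XWX_inv = []
        self._logdet = np.empty(self.lam_grid.size)
        for k, lam in enumerate(self.lam_grid):
            c = lam / (1.0 + lam * self.sizes)
            XWX = XtX - self.GX.T @ (c[:, None] * self.GX)
            self._c.append(c)
            self._A.append((self.GX * c[:, None]).T)
            self._cho.append(linalg.cho_factor(XWX))
            self._XWX_inv.append(linalg.inv(XWX))
            self._logdet[k] = np.sum(np.log1p(lam * self.sizes))

    def fit_many(self, Y: np.ndarray) -> dict:
        """Fit every column of ``Y`` (n_obs x m); returns stacked estimates."""
        Y = np.asarray(Y, float)
        n, m = Y.shape
        if n != self.n_obs:
            raise ValueError("Y rows do not match the design")
        GY = np.add.reduceat(Y, self.starts, axis=0)
        XtY = self.X.T @ Y
        YtY = np.einsum("ij,ij->j", Y, Y)
        L = self.lam_grid.size
        ll = np.empty((L, m))
        betas = np.empty((L, self.n_params, m))
        rss_all = np.empty((L, m))
        for k in range(L):
            c = self._c[k]
            XWY = XtY - self._A[k] @ GY
            yWy = YtY - c @ (GY**2)
            beta = linalg.cho_solve(self._cho[k], XWY)
            rss = yWy - np.einsum("pm,pm->m", beta, XWY)
            rss = np.maximum(rss, 1e-300)
            ll[k] = -0.5 * (n * (_LOG_2PI + np.log(rss / n)) + self._logdet[k] + n)
            betas[k] = beta
            rss_all[k] = rss
        best = np.argmax(ll, axis=0)
        cols = np.arange(m)
        sigma_e2 = rss_all[best, cols] / n
        lam = self.lam_grid[best]
        return {
            "beta": betas[best, :, cols].T,  # (p, m)
            "sigma_e2": sigma_e2,
            "sigma_b2": lam * sigma_e2,
            "lam": lam,
            "lam_index": best,
            "loglik": ll[best, cols],
        }

    def contrast_z(self, fit: dict, weights: np.ndarray):
        """Wald estimate/SE/Z of ``w' beta`` for every fitted column."""
        w = np.asarray(weights, float)
        q = np.array([w @ inv @ w for inv in self._XWX_inv])
        est = w @ fit["beta"]
        se = np.sqrt(fit["sigma_e2"] * q[fit["lam_index"]])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        return est, se, z

    def simulate(
        self,
        beta: np.ndarray,
        sigma_b: np.ndarray,
        sigma_e: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Draw outcome columns from the model on this exact design.

        ``beta`` is (p, m); ``sigma_b``/``sigma_e`` broadcast over the m
        columns.  The observed missingness pattern is reproduced by
        construction since the design rows are reused as-is.
        """
        beta = np.asarray(beta, float)
        m = beta.shape[1]
        mean = self.X @ beta
        b = rng.standard_normal((self.sizes.size, m)) * np.atleast_1d(sigma_b)
        e = rng.standard_normal((self.n_obs, m)) * np.atleast_1d(sigma_e)
        return mean + np.repeat(b, self.sizes, axis=0) + e
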