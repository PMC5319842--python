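"""Regularized cubic smoothing splines for temporal expression profiles.

The curve model is the classical natural cubic smoothing spline: among all
twice-differentiable functions, minimize

    sum_i (y_i - f(x_i))^2 + lam * integral f''(u)^2 du .

The minimizer is a natural cubic spline with knots at the data points, and
its knot values are a *linear* function of the observations,
``f = (I + lam*K)^{-1} y`` with the Green--Silverman roughness matrix
``K = Q R^{-1} Q^T``.  Linearity gives two things the point-selection search
relies on: an exact closed-form leave-one-out cross-validation error from
the hat-matrix diagonal, and vectorization of the fit across all genes at
once (see :mod:`tpselect.selection`).

The public fitting interface parameterizes smoothness the way practitioners
state it for approximating splines: an upper bound ``s`` on the residual sum
of squares, with the penalty adjusted until the bound is met exactly
(``s = 0`` interpolates; very large ``s`` collapses to the least-squares
straight line).  The two parameterizations are duals of the same problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SplineModel",
    "SmoothingSelection",
    "fit_spline",
    "select_smoothing_loocv",
    "reconstruct",
    "piecewise_linear_reconstruct",
    "natural_spline_system",
    "natural_eval_matrix",
    "default_s_grid",
]


# -- Green--Silverman machinery ----------------------------------------------


def natural_spline_system(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Roughness matrix ``K`` and the map from knot values to interior
    second derivatives (``R^{-1} Q^T``) for knots ``x``.

    For k = 2 knots there is no curvature: both are empty/zero.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    if k < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("times must be strictly increasing")
    if k == 2:
        return np.zeros((2, 2)), np.zeros((0, 2))
    h = np.diff(x)
    Q = np.zeros((k, k - 2))
    R = np.zeros((k - 2, k - 2))
    for j in range(1, k - 1):
        i = j - 1
        Q[j - 1, i] = 1.0 / h[j - 1]
        Q[j, i] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, i] = 1.0 / h[j]
        R[i, i] = (h[j - 1] + h[j]) / 3.0
        if j < k - 2:
            R[i, i + 1] = R[i + 1, i] = h[j] / 6.0
    rinv_qt = np.linalg.solve(R, Q.T)
    return Q @ rinv_qt, rinv_qt


def natural_eval_matrix(
    x: np.ndarray, rinv_qt: np.ndarray, query: np.ndarray
) -> np.ndarray:
    """Matrix ``A`` with ``A @ f`` = natural-spline interpolant of (x, f)
    evaluated at ``query`` (query must lie within [x[0], x[-1]])."""
    x = np.asarray(x, dtype=float)
    q = np.atleast_1d(np.asarray(query, dtype=float))
    if q.size and (q.min() < x[0] - 1e-12 or q.max() > x[-1] + 1e-12):
        raise ValueError("query times outside the fitted range (no extrapolation)")
    k = x.size
    gamma = np.zeros((k, k))  # knot values -> 2nd derivatives (natural ends = 0)
    if k > 2:
        gamma[1:-1, :] = rinv_qt
    idx = np.clip(np.searchsorted(x, q, side="right") - 1, 0, k - 2)
    xl, xr = x[idx], x[idx + 1]
    h = xr - xl
    a = (xr - q) / h
    b = (q - xl) / h
    A = np.zeros((q.size, k))
    rows = np.arange(q.size)
    A[rows, idx] += a
    A[rows, idx + 1] += b
    c = (a**3 - a) * h**2 / 6.0
    d = (b**3 - b) * h**2 / 6.0
    A += c[:, None] * gamma[idx, :] + d[:, None] * gamma[idx + 1, :]
    return A


def _fit_values(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Fitted knot values of the penalized spline for one curve."""
    if not np.isfinite(lam):  # limit: ordinary least-squares line
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ beta
    K, _ = natural_spline_system(x)
    return np.linalg.solve(np.eye(x.size) + lam * K, y)


# -- public fitting interface -------------------------------------------------


@dataclass
class SplineModel:
    """A fitted smoothing spline for one gene over a point subset.

    ``knots`` are the fitted times, ``values`` the fitted (smoothed) knot
    values; evaluation is natural cubic interpolation of these, defined only
    on [knots[0], knots[-1]].
    """

    knots: np.ndarray
    values: np.ndarray
    s: float
    lam: float
    gene_id: str | None = None

    def __post_init__(self) -> None:
        _, self._rinv_qt = natural_spline_system(self.knots)

    def predict(self, query_times) -> np.ndarray:
        A = natural_eval_matrix(self.knots, self._rinv_qt, query_times)
        return A @ self.values


def fit_spline(
    times, values, s: float, gene_id: str | None = None
) -> SplineModel:
    """Fit a cubic smoothing spline with residual sum of squares <= ``s``.

    The roughness penalty is raised (by bisection on log-penalty) until the
    residual bound is active, i.e. the smoothest curve whose RSS does not
    exceed ``s``.  ``s = 0`` gives the interpolating natural spline; ``s``
    at or above the straight-line RSS gives the least-squares line.  With 2
    points the fit is the connecting line; with 3 points the natural cubic
    through/near them (the cubic is not over-parameterized because the
    natural boundary conditions remove two degrees of freedom).
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 points to fit a spline")
    if x.shape != y.shape:
        raise ValueError("times and values must have the same length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("times must be strictly increasing")
    if s < 0:
        raise ValueError("smoothing parameter s must be >= 0")

    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_line = float(np.sum((y - X @ beta) ** 2))

    if x.size == 2 or s <= 1e-14 or rss_line <= 1e-14:
        # two points, an exact bound, or (near-)collinear data: interpolate
        return SplineModel(x, y.copy(), s=s, lam=0.0, gene_id=gene_id)
    if s >= rss_line:
        return SplineModel(x, X @ beta, s=s, lam=np.inf, gene_id=gene_id)

    K, _ = natural_spline_system(x)
    eye = np.eye(x.size)

    def rss_of(loglam: float) -> float:
        f = np.linalg.solve(eye + np.exp(loglam) * K, y)
        return float(np.sum((y - f) ** 2))

    lo, hi = -30.0, 30.0
    while rss_of(hi) < s and hi < 80:
        hi += 10.0
    if rss_of(hi) < s:  # numerically indistinguishable from the line
        return SplineModel(x, X @ beta, s=s, lam=np.inf, gene_id=gene_id)
    while rss_of(lo) > s and lo > -80:
        lo -= 10.0
    loglam = brentq(lambda ll: rss_of(ll) - s, lo, hi, xtol=1e-10)
    lam = float(np.exp(loglam))
    return SplineModel(x, _fit_values(x, y, lam), s=s, lam=lam, gene_id=gene_id)


def reconstruct(model: SplineModel, query_times) -> np.ndarray:
    """Evaluate a fitted spline; no extrapolation beyond the endpoints."""
    return model.predict(query_times)


# -- smoothing-parameter selection by LOOCV -----------------------------------


def default_s_grid(times, values, n: int = 15) -> np.ndarray:
    """Geometric grid of RSS bounds spanning [1e-3, 1e2] x residual scale.

    The scale is the straight-line residual sum of squares of the profile,
    so the grid brackets everything from near-interpolation to the linear
    fit regardless of the gene's expression units.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = max(float(np.sum((y - X @ beta) ** 2)), 1e-10)
    return np.geomspace(1e-3, 1e2, n) * scale


@dataclass
class SmoothingSelection:
    s: float
    s_grid: np.ndarray
    cv_errors: np.ndarray


def select_smoothing_loocv(times, values, s_grid=None) -> SmoothingSelection:
    """Choose the residual bound ``s`` by leave-one-out cross-validation.

    Each interior point is left out in turn (the endpoints are never
    dropped, mirroring the selection rule that the first and last time
    points are always profiled), the spline refitted to the remainder with
    the same bound, and the squared prediction error at the left-out point
    accumulated.  Ties are broken toward the larger (smoother) ``s``.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("LOOCV needs >= 5 points (interior folds of >= 4)")
    if s_grid is None:
        s_grid = default_s_grid(x, y)
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty smoothing grid")
    cv = np.zeros(s_grid.size)
    for j, s in enumerate(s_grid):
        err = 0.0
        for i in range(1, x.size - 1):
            xs = np.delete(x, i)
            ys = np.delete(y, i)
            model = fit_spline(xs, ys, s=float(s))
            err += float((model.predict([x[i]])[0] - y[i]) ** 2)
        cv[j] = err
    best = np.flatnonzero(cv <= cv.min() + 1e-12)[-1]  # tie -> smoother
    return SmoothingSelection(s=float(s_grid[best]), s_grid=s_grid, cv_errors=cv)


# -- baseline reconstructor ---------------------------------------------------


def piecewise_linear_reconstruct(times, values, query_times) -> np.ndarray:
    """Linear interpolation between consecutive selected points.

    Emulates the implicit reconstruction of conventional sparse designs
    (connect-the-dots between the profiled times); no extrapolation.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("times must be strictly increasing")
    if q.size and (q.min() < x[0] - 1e-12 or q.max() > x[-1] + 1e-12):
        raise ValueError("query times outside the selected range")
    return np.interp(q, x, y)
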