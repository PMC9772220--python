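"""Zero-order Tikhonov regularization with L-curve parameter selection.

Solves ``argmin_s ||b - A s||^2 + lambda ||s||^2`` through the normal
equations (or an SVD factored once and reused across a lambda sweep), and
selects lambda at the corner — the point of maximum signed curvature — of
the L-curve, the log-log plot of solution norm against residual norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, svd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LCurvePoint",
    "LCurveCorner",
    "TikhonovResult",
    "solve_tikhonov",
    "lcurve_sweep",
    "lcurve_corner",
    "default_lambda_grid",
    "TikhonovRegression",
]


@dataclass
class LCurvePoint:
    lam: float
    residual_norm: float
    solution_norm: float


@dataclass
class LCurveCorner:
    """Corner of an L-curve: lambda at maximum signed log-log curvature.

    ``distinct`` is False when no point on the curve has appreciable
    curvature (e.g. a straight line in log-log space), in which case
    ``lam`` is still the curvature argmax but should be treated with care.
    """

    lam: float
    index: int
    curvature: float
    distinct: bool


@dataclass
class TikhonovResult:
    estimate: np.ndarray  # Q x T
    lam: float
    residual_norms: np.ndarray  # per instant
    solution_norms: np.ndarray  # per instant


def solve_tikhonov(A: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Ridge solution of (A'A + lam I) s = A'b.

    ``b`` may have multiple columns (time instants), solved jointly.
    The residual convention is ``b - A s``: the additive noise term of the
    data model is not subtractable at inversion time.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lam must be a positive finite number")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in A or b")
    if A.shape[0] != b.shape[0]:
        raise ValueError("A and b row counts differ")
    q = A.shape[1]
    gram = A.T @ A + lam * np.eye(q)
    return cho_solve(cho_factor(gram, lower=True), A.T @ b)


def default_lambda_grid(
    lo: float = 1e-10, hi: float = 10.0, num: int = 100, spacing: str = "linear"
) -> np.ndarray:
    """Regularization grid; the default is 100 linearly spaced values on
    [1e-10, 10], with geometric spacing as an option."""
    if spacing == "linear":
        return np.linspace(lo, hi, num)
    if spacing == "log":
        return np.geomspace(lo, hi, num)
    raise ValueError("spacing must be 'linear' or 'log'")


def lcurve_sweep(
    A: np.ndarray, b: np.ndarray, lambda_grid: np.ndarray
) -> list[LCurvePoint]:
    """Residual and solution norms across a lambda grid (SVD factored once).

    For multi-column ``b`` the norms are Frobenius norms over all columns.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(lambda_grid <= 0) or np.any(np.diff(lambda_grid) <= 0):
        raise ValueError("lambda grid must be positive and strictly ascending")
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    u, sig, vt = svd(A, full_matrices=False)
    utb = u.T @ b
    points = []
    for lam in lambda_grid:
        filt = sig / (sig**2 + lam)
        coef = filt[:, None] * utb if utb.ndim == 2 else filt * utb
        sol_norm = float(np.linalg.norm(coef))  # V is orthogonal
        resid = b - u @ ((sig[:, None] if utb.ndim == 2 else sig) * coef)
        points.append(LCurvePoint(float(lam), float(np.linalg.norm(resid)), sol_norm))
    return points


def lcurve_corner(
    points: list[LCurvePoint], curvature_floor: float = 1e-6
) -> LCurveCorner:
    """Maximum signed curvature of the log-log L-curve polyline.

    Curvature at each interior point is the signed Menger curvature of the
    circumscribed circle through it and its neighbours in (log residual,
    log solution norm) coordinates; the sign convention makes the convex
    corner of an L positive.  Ties break toward the smaller lambda.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 L-curve points")
    x = np.log(np.maximum([p.residual_norm for p in points], 1e-300))
    y = np.log(np.maximum([p.solution_norm for p in points], 1e-300))
    curv = np.full(len(points), -np.inf)
    for i in range(1, len(points) - 1):
        a = np.array([x[i] - x[i - 1], y[i] - y[i - 1]])
        c = np.array([x[i + 1] - x[i], y[i + 1] - y[i]])
        cross = a[0] * c[1] - a[1] * c[0]
        la, lc = np.linalg.norm(a), np.linalg.norm(c)
        lb = np.linalg.norm(a + c)
        denom = la * lc * lb
        curv[i] = 2.0 * cross / denom if denom > 0 else 0.0
    idx = int(np.argmax(curv))  # first (smallest lambda) on ties
    return LCurveCorner(
        points[idx].lam, idx, float(curv[idx]), bool(curv[idx] > curvature_floor)
    )


class TikhonovRegression(BaseEstimator, RegressorMixin):
    """Ridge-type inverse solver with optional L-curve lambda selection.

    Parameters
    ----------
    lam : float or "auto"
        Regularization parameter; ``"auto"`` selects the L-curve corner
        over ``lambda_grid`` (norms pooled over all target columns).
    lambda_lo, lambda_hi, lambda_num, lambda_spacing :
        Grid for the sweep; default 100 linearly spaced values on
        [1e-10, 10].

    Attributes
    ----------
    coef_ : (n_targets, n_features) or (n_features,)
        Estimated sources per time instant.
    lambda_ : float
        Regularization parameter actually used.
    lcurve_points_ : list of LCurvePoint, only when lam="auto".
    lcurve_corner_ : LCurveCorner, only when lam="auto".
    """

    def __init__(
        self,
        lam: float | str = "auto",
        lambda_lo: float = 1e-10,
        lambda_hi: float = 10.0,
        lambda_num: int = 100,
        lambda_spacing: str = "linear",
    ):
        self.lam = lam
        self.lambda_lo = lambda_lo
        self.lambda_hi = lambda_hi
        self.lambda_num = lambda_num
        self.lambda_spacing = lambda_spacing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        if self.lam == "auto":
            grid = default_lambda_grid(
                self.lambda_lo, self.lambda_hi, self.lambda_num, self.lambda_spacing
            )
            self.lcurve_points_ = lcurve_sweep(X, y, grid)
            self.lcurve_corner_ = lcurve_corner(self.lcurve_points_)
            self.lambda_ = self.lcurve_corner_.lam
        else:
            self.lambda_ = float(self.lam)
        est = solve_tikhonov(X, y, self.lambda_)
        self.coef_ = est.T if est.ndim == 2 else est
        resid = y - X @ est
        self.residual_norms_ = np.linalg.norm(np.atleast_2d(resid.T), axis=1)
        self.solution_norms_ = np.linalg.norm(np.atleast_2d(est.T), axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ np.asarray(self.coef_).T

    def result_(self) -> TikhonovResult:
        est = np.asarray(self.coef_)
        est = est.T if est.ndim == 2 else est[:, None]
        return TikhonovResult(
            est, self.lambda_, self.residual_norms_, self.solution_norms_
        )
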