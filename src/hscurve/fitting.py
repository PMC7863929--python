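"""Weighted robust quartic fits of ROI curves.

Each pruned ROI curve (x = window mean, y = window standard deviation) is
fitted with a quartic polynomial

    f(x, b) = b0*x^4 + b1*x^3 + b2*x^2 + b3*x + b4

by minimizing the weighted sum of squares  sum_i w_i (y_i - f(x_i, b))^2,
with fixed observation weights from the heteroscedasticity model

    w(y) = 1 / (0.011 + 0.011*y)^2

(evaluated at the observed y_i: low-variance points are trusted more), and
an optional bisquare iteratively-reweighted-least-squares (IRLS) layer on
top that down-weights outlying points.  Abscissae are standardized
internally for conditioning; reported coefficients are in the original x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConditioningError, IdentifiabilityError
from .roi import PrunedCurve, ROICurve

__all__ = ["FitOptions", "QuarticFit", "weight", "fit_quartic", "eval_fit", "mse", "weighted_objective"]

_DEGREE = 4


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the weighted robust quartic fit.

    weight_c1, weight_c2
        Constants of the weight function w(y) = 1/(c1 + c2*y)^2.
    max_iter, tol
        IRLS iteration cap and convergence tolerance on the maximum
        absolute coefficient change (in original-x coefficients).
    robust
        Enable bisquare reweighting; with False the fit is a single
        closed-form weighted least-squares solve.
    bisquare_tuning
        Tuning constant of the bisquare psi (4.685 gives 95% Gaussian
        efficiency).
    weight_on
        Where the weight function is evaluated: the observed y_i
        (default; fixed deterministic weights) or the current fitted
        response (recomputed each IRLS pass).
    """

    weight_c1: float = 0.011
    weight_c2: float = 0.011
    max_iter: int = 100
    tol: float = 1e-8
    robust: bool = True
    bisquare_tuning: float = 4.685
    weight_on: str = "observed"

    def __post_init__(self) -> None:
        if self.weight_c1 <= 0 or self.weight_c2 <= 0:
            raise ValueError("weight constants must be positive")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.weight_on not in ("observed", "fitted"):
            raise ValueError("weight_on must be 'observed' or 'fitted'")


@dataclass
class QuarticFit:
    """Result of one quartic fit.

    ``coeffs`` is (b0, b1, b2, b3, b4), highest power first.  ``objective``
    is the final base-weighted sum of squared residuals; ``mse`` the
    unweighted mean squared residual over the fitted points.
    """

    coeffs: tuple[float, float, float, float, float]
    x_range: tuple[float, float]
    converged: bool
    n_iter: int
    objective: float
    mse: float
    n_points: int

    def __call__(self, x):
        return np.polyval(self.coeffs, x)


def weight(y, c1: float = 0.011, c2: float = 0.011):
    """Observation weight w(y) = 1/(c1 + c2*y)^2, strictly decreasing in y >= 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("standard deviations must be nonnegative")
    w = 1.0 / (c1 + c2 * y) ** 2
    return float(w) if w.ndim == 0 else w


def _bisquare(u: np.ndarray) -> np.ndarray:
    r = np.zeros_like(u)
    inside = np.abs(u) < 1
    r[inside] = (1 - u[inside] ** 2) ** 2
    return r


def _back_transform_matrix(xm: float, xs: float) -> np.ndarray:
    """Linear map from coefficients in z = (x - xm)/xs to coefficients in x."""
    T = np.zeros((_DEGREE + 1, _DEGREE + 1))
    lin = np.poly1d([1.0 / xs, -xm / xs])
    acc = np.poly1d([1.0])
    for k in range(_DEGREE, -1, -1):  # z^k column for coefficient slot of z^k
        T[_DEGREE - acc.order :, k] = acc.coeffs
        acc = acc * lin
    return T


def fit_quartic(curve: PrunedCurve | ROICurve, opts: FitOptions | None = None) -> QuarticFit:
    """Fit the weighted (optionally robust) quartic to a curve.

    Needs at least 5 distinct x values.  On non-convergence the best
    iterate is returned with ``converged=False`` rather than raising.

    Raises
    ------
    IdentifiabilityError
        Fewer than 5 distinct abscissae.
    ConditioningError
        The weighted design is rank-deficient even after standardization.
    """
    opts = opts or FitOptions()
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    n = x.size
    if np.unique(x).size < _DEGREE + 1:
        raise IdentifiabilityError(
            f"quartic needs >= 5 distinct x values, got {np.unique(x).size}"
        )
    x_range = (float(x.min()), float(x.max()))
    w_base = weight(y, opts.weight_c1, opts.weight_c2)

    if np.ptp(y) == 0.0:
        # constant response: the constant polynomial is the exact minimizer
        coeffs = np.array([0.0, 0.0, 0.0, 0.0, float(y[0])])
        return QuarticFit(tuple(coeffs), x_range, True, 0, 0.0, 0.0, n)

    xm, xs = float(x.mean()), float(x.std())
    z = (x - xm) / xs
    X = np.vander(z, _DEGREE + 1)
    T = _back_transform_matrix(xm, xs)

    r_rob = np.ones(n)
    coeffs_prev: np.ndarray | None = None
    coeffs = np.zeros(_DEGREE + 1)
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        sw = np.sqrt(w_base * r_rob)
        sol, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if rank < _DEGREE + 1:
            raise ConditioningError(
                "weighted design is rank-deficient; check for near-duplicate x values"
            )
        coeffs = T @ sol
        if coeffs_prev is not None and np.max(np.abs(coeffs - coeffs_prev)) < opts.tol:
            converged = True
            break
        coeffs_prev = coeffs
        if opts.weight_on == "fitted":
            w_base = weight(np.clip(X @ sol, 0.0, None), opts.weight_c1, opts.weight_c2)
        elif not opts.robust:
            converged = True
            break
        if opts.robust:
            resid_w = np.sqrt(w_base) * (y - X @ sol)
            scale = np.median(np.abs(resid_w)) / 0.6745
            if scale == 0.0:
                converged = True
                break
            r_new = _bisquare(resid_w / (opts.bisquare_tuning * scale))
            if np.count_nonzero(r_new) < _DEGREE + 1:
                break  # degenerate reweighting; keep current iterate
            r_rob = r_new

    fitted = np.polyval(coeffs, x)
    resid = y - fitted
    return QuarticFit(
        coeffs=tuple(float(c) for c in coeffs),
        x_range=x_range,
        converged=converged,
        n_iter=n_iter,
        objective=float(np.sum(w_base * resid**2)),
        mse=float(np.mean(resid**2)),
        n_points=n,
    )


def eval_fit(fit: QuarticFit, x):
    """Fitted value and analytic first/second derivatives at x.

    f'(x) = 4 b0 x^3 + 3 b1 x^2 + 2 b2 x + b3
    f''(x) = 12 b0 x^2 + 6 b1 x + 2 b2
    """
    c = np.asarray(fit.coeffs)
    d1 = np.polyder(c)
    d2 = np.polyder(c, 2)
    return np.polyval(c, x), np.polyval(d1, x), np.polyval(d2, x)


def mse(fit: QuarticFit, curve: PrunedCurve | ROICurve) -> float:
    """Unweighted mean squared residual of the fit over the curve's points."""
    resid = np.asarray(curve.y, dtype=float) - fit(np.asarray(curve.x, dtype=float))
    return float(np.mean(resid**2))


def weighted_objective(fit: QuarticFit, curve: PrunedCurve | ROICurve,
                       opts: FitOptions | None = None) -> float:
    """Base-weighted sum of squared residuals (the quantity the fit minimizes)."""
    opts = opts or FitOptions()
    y = np.asarray(curve.y, dtype=float)
    resid = y - fit(np.asarray(curve.x, dtype=float))
    return float(np.sum(weight(y, opts.weight_c1, opts.weight_c2) * resid**2))
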