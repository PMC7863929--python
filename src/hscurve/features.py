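"""Derivative-based features of fitted ROI curves and per-cube summaries.

The decision rules consume a handful of scalar features of each fitted
quartic f, evaluated at the curve's own abscissae x_1..x_n:

    df_mean   mean of f'(x_i)              (slope of std vs. mean)
    ddf_mean  mean of f''(x_i)             (curvature)
    df_at_max f' at the x_i where f is largest
    totm      a*df_mean + b*ddf_mean + df_at_max   (melanoma score; a=1, b=0.1)
    mean      mean of f(x_i)               (typical std level)
    mabdf     mean + mean|f'(x_i)|         (benign score)
    prod      max(x_i) * max f(x_i)

Melanoma curves are steep and convex (large totm); other malignant lesions
sit at elevated std (large mean or prod); benign lesions are flat and low
(small mean and mabdf).  Per cube, the relevant extrema over all candidate
windows feed the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .fitting import QuarticFit, eval_fit
from .roi import PrunedCurve, ROICurve, ROIWindow

__all__ = ["CurveFeatures", "CubeFeatureSummary", "compute_features", "summarize_cube"]


@dataclass
class CurveFeatures:
    """Scalar features of one fitted curve (see module docstring)."""

    df_mean: float
    ddf_mean: float
    df_at_max: float
    totm: float
    mean: float
    abs_df_mean: float
    mabdf: float
    prod: float
    inflections: int
    window: ROIWindow | None = None
    cube_id: str = ""


@dataclass
class CubeFeatureSummary:
    """Extrema of the classifier-relevant features over one cube's candidate curves."""

    max_totm: float
    max_mean: float
    max_prod: float
    min_mean: float
    min_mabdf: float
    arg_windows: dict[str, tuple[int, int] | None]
    n_curves: int


def _count_inflections(coeffs: Sequence[float], x_lo: float, x_hi: float) -> int:
    """Sign changes of f'' strictly inside (x_lo, x_hi); always 0, 1 or 2."""
    b0, b1, b2, _, _ = coeffs
    a, b, c = 12.0 * b0, 6.0 * b1, 2.0 * b2
    if a == 0.0:
        if b == 0.0:
            return 0
        root = -c / b
        return 1 if x_lo < root < x_hi else 0
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return 0  # no real roots, or a double root (no sign change)
    sq = np.sqrt(disc)
    return sum(1 for r in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if x_lo < r < x_hi)


def compute_features(
    fit: QuarticFit,
    curve: PrunedCurve | ROICurve,
    a: float = 1.0,
    b: float = 0.1,
    totm_variant: Literal["text", "figure"] = "text",
    eval_points: int | None = None,
) -> CurveFeatures:
    """Evaluate all curve features at the curve's own x points.

    ``totm_variant='text'`` (default) includes the derivative at the fitted
    maximum, ``totm = a*df_mean + b*ddf_mean + df_at_max``; ``'figure'``
    drops the last term.  ``eval_points`` switches evaluation from the
    curve's observed abscissae to a dense equispaced grid of that size
    spanning the same x-range.
    """
    x = np.asarray(curve.x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute features of an empty curve")
    if eval_points is not None:
        x = np.linspace(x.min(), x.max(), eval_points)
    f, df, ddf = eval_fit(fit, x)
    i_max = int(np.argmax(f))
    df_mean = float(df.mean())
    ddf_mean = float(ddf.mean())
    df_at_max = float(df[i_max])
    totm = a * df_mean + b * ddf_mean
    if totm_variant == "text":
        totm += df_at_max
    elif totm_variant != "figure":
        raise ValueError(f"unknown totm_variant {totm_variant!r}")
    mean = float(f.mean())
    abs_df_mean = float(np.abs(df).mean())
    return CurveFeatures(
        df_mean=df_mean,
        ddf_mean=ddf_mean,
        df_at_max=df_at_max,
        totm=totm,
        mean=mean,
        abs_df_mean=abs_df_mean,
        mabdf=mean + abs_df_mean,
        prod=float(x.max() * f.max()),
        inflections=_count_inflections(fit.coeffs, float(x.min()), float(x.max())),
        window=getattr(curve, "window", None),
        cube_id=getattr(curve, "cube_id", ""),
    )


def _center(feat: CurveFeatures) -> tuple[int, int]:
    return feat.window.center if feat.window is not None else (0, 0)


def summarize_cube(features_list: Sequence[CurveFeatures]) -> CubeFeatureSummary:
    """Extrema of (totm, mean, prod, mabdf) over a cube's candidate curves.

    Ties are broken deterministically toward the lowest (row, col) window
    center, so summaries are independent of input order.
    """
    if len(features_list) == 0:
        raise ValueError("cannot summarize an empty feature list")

    def pick(attr: str, biggest: bool) -> CurveFeatures:
        def key(f: CurveFeatures):
            v = getattr(f, attr)
            return ((-v if biggest else v), _center(f))

        return min(features_list, key=key)

    best = {
        "max_totm": pick("totm", True),
        "max_mean": pick("mean", True),
        "max_prod": pick("prod", True),
        "min_mean": pick("mean", False),
        "min_mabdf": pick("mabdf", False),
    }
    return CubeFeatureSummary(
        max_totm=best["max_totm"].totm,
        max_mean=best["max_mean"].mean,
        max_prod=best["max_prod"].prod,
        min_mean=best["min_mean"].mean,
        min_mabdf=best["min_mabdf"].mabdf,
        arg_windows={
            k: (f.window.center if f.window is not None else None) for k, f in best.items()
        },
        n_curves=len(features_list),
    )
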