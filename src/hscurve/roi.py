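"""Sliding 7x7 ROI sweep, per-band mean/std curves, and curve pruning.

For a window fixed in space, each spectral band contributes one point
(x = within-window mean reflectance, y = within-window standard deviation).
Traversing the bands traces out an *ROI curve* in the mean/std plane — the
object this package classifies.  The default sweep slides the window center
over the inclusive grid (16,16)..(35,35) in the instrument's 1-based pixel
convention, giving 20 x 20 = 400 candidate curves whose footprints jointly
cover a 26 x 26 pixel square (rows/cols 13..38, 1-based).

Curves whose x backtracks a lot ("convoluted" curves) are thinned before
fitting: the x-range is binned and each nonempty bin is replaced by its
median-y point, which both orders the curve in x and suppresses spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import GeometryError
from .io import HSICube

__all__ = ["ROIWindow", "ROICurve", "PrunedCurve", "window_stats", "sweep", "complexity", "prune"]


@dataclass(frozen=True)
class ROIWindow:
    """Square pixel window given by its center (0-based row, col) and odd side length."""

    center: tuple[int, int]
    side: int = 7

    def __post_init__(self) -> None:
        if self.side % 2 != 1 or self.side < 1:
            raise GeometryError(f"window side must be odd and positive, got {self.side}")

    @classmethod
    def from_one_based(cls, center: tuple[int, int], side: int = 7) -> "ROIWindow":
        """Build from the 1-based (x, y) pixel convention of the acquisition software."""
        return cls(center=(center[0] - 1, center[1] - 1), side=side)

    @property
    def half(self) -> int:
        return self.side // 2

    def bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open slices of the footprint."""
        r, c = self.center
        h = self.half
        return r - h, r + h + 1, c - h, c + h + 1

    def check_inside(self, shape: tuple[int, ...]) -> None:
        r0, r1, c0, c1 = self.bounds()
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise GeometryError(
                f"window centered at {self.center} (side {self.side}) exceeds spatial extent {shape[:2]}"
            )


@dataclass
class ROICurve:
    """The (mean, std) locus of one window across all bands, in band order."""

    x: np.ndarray  # per-band window mean
    y: np.ndarray  # per-band window standard deviation
    window: ROIWindow
    cube_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class PrunedCurve:
    """An ROI curve reduced to strictly increasing x, ready for fitting."""

    x: np.ndarray
    y: np.ndarray
    kept_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pruned: bool = False
    window: ROIWindow | None = None
    cube_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size == 0:
            raise ValueError("pruned curve must be nonempty")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("pruned curve x must be strictly increasing")

    def __len__(self) -> int:
        return self.x.size


def window_stats(cube: HSICube, window: ROIWindow, ddof: int = 1) -> ROICurve:
    """Per-band mean and standard deviation of the pixels under one window.

    The standard deviation is the sample estimate (denominator N - ddof,
    default ddof=1) over the side**2 pixel values of each band.
    """
    window.check_inside(cube.data.shape)
    r0, r1, c0, c1 = window.bounds()
    block = cube.data[r0:r1, c0:c1, :].reshape(-1, cube.n_bands)
    return ROICurve(
        x=block.mean(axis=0),
        y=block.std(axis=0, ddof=ddof),
        window=window,
        cube_id=cube.id,
    )


def sweep(
    cube: HSICube,
    start: tuple[int, int] = (16, 16),
    end: tuple[int, int] = (35, 35),
    stride: int = 1,
    side: int = 7,
    one_based: bool = True,
    ddof: int = 1,
) -> list[ROICurve]:
    """All ROI curves on the inclusive center grid ``start..end``.

    ``start`` and ``end`` follow the 1-based pixel convention by default
    (the instrument's coordinates); pass ``one_based=False`` for 0-based
    array indices.  Defaults give 400 curves on a 50x50 cube.
    """
    off = 1 if one_based else 0
    r_lo, c_lo = start[0] - off, start[1] - off
    r_hi, c_hi = end[0] - off, end[1] - off
    if r_hi < r_lo or c_hi < c_lo or stride < 1:
        raise GeometryError(f"invalid sweep grid {start}..{end} stride {stride}")
    half = side // 2
    rows, cols, _ = cube.data.shape
    for r in (r_lo, r_hi):
        for c in (c_lo, c_hi):
            w = ROIWindow(center=(r, c), side=side)
            try:
                w.check_inside(cube.data.shape)
            except GeometryError as err:
                raise GeometryError(f"sweep grid leaves bounds: {err}") from err

    # One vectorized pass over exactly the swept window positions.
    view = sliding_window_view(cube.data, (side, side), axis=(0, 1))  # (R-s+1, C-s+1, b, s, s)
    view = view[r_lo - half : r_hi - half + 1 : stride, c_lo - half : c_hi - half + 1 : stride]
    flat = view.reshape(view.shape[0], view.shape[1], cube.n_bands, side * side)
    means = flat.mean(axis=3)
    stds = flat.std(axis=3, ddof=ddof)

    curves: list[ROICurve] = []
    for i, r in enumerate(range(r_lo, r_hi + 1, stride)):
        for j, c in enumerate(range(c_lo, c_hi + 1, stride)):
            curves.append(
                ROICurve(
                    x=means[i, j].copy(),
                    y=stds[i, j].copy(),
                    window=ROIWindow(center=(r, c), side=side),
                    cube_id=cube.id,
                )
            )
    return curves


def complexity(curve: ROICurve) -> float:
    """How much the curve's x backtracks along band order.

    Total variation of x divided by its range: 1.0 for x monotone in band
    order, larger the more the curve folds over itself, +inf for a
    degenerate zero-x-range curve.
    """
    if len(curve) < 2:
        raise ValueError("complexity needs at least 2 points")
    rng = float(curve.x.max() - curve.x.min())
    if rng == 0.0:
        return float("inf")
    return float(np.abs(np.diff(curve.x)).sum() / rng)


def _collapse_duplicates(x: np.ndarray, y: np.ndarray, idx: np.ndarray):
    xs, ys, keep = [], [], []
    ux = np.unique(x)
    for v in ux:
        mask = x == v
        xs.append(v)
        ys.append(float(np.median(y[mask])))
        keep.append(int(idx[mask][0]))
    return np.array(xs), np.array(ys), np.array(keep, dtype=int)


def prune(curve: ROICurve, threshold: float = 3.0, bins: int = 50) -> PrunedCurve:
    """Order a curve by x, thinning convoluted ones.

    Simple curves (complexity <= ``threshold``) are just sorted by x with
    exact-duplicate x collapsed to their median y.  Convoluted curves are
    binned into ``bins`` equal x-intervals; each nonempty bin contributes
    one point (mean x, median y) — a 1-D thinning that erodes spikes the
    way a grayscale morphological filter would.  Output x is strictly
    increasing and never has more points than the input.
    """
    x, y = curve.x, curve.y
    order = np.argsort(x, kind="stable")
    xs, ys, idx = x[order], y[order], order
    rng = float(xs[-1] - xs[0])
    comp = complexity(curve) if len(curve) >= 2 else 1.0

    if rng == 0.0:
        # all x identical: collapse to the single median point
        px, py, keep = _collapse_duplicates(xs, ys, idx)
        return PrunedCurve(px, py, keep, pruned=False, window=curve.window, cube_id=curve.cube_id)

    if comp <= threshold:
        px, py, keep = _collapse_duplicates(xs, ys, idx)
        return PrunedCurve(px, py, keep, pruned=False, window=curve.window, cube_id=curve.cube_id)

    edges = np.linspace(xs[0], xs[-1], bins + 1)
    which = np.clip(np.digitize(xs, edges[1:-1], right=False), 0, bins - 1)
    px, py, keep = [], [], []
    for b in range(bins):
        mask = which == b
        if not mask.any():
            continue
        ym = float(np.median(ys[mask]))
        px.append(float(xs[mask].mean()))
        py.append(ym)
        # representative original band: member whose y is closest to the bin median
        sub = np.flatnonzero(mask)
        keep.append(int(idx[sub[np.argmin(np.abs(ys[mask] - ym))]]))
    return PrunedCurve(
        np.array(px), np.array(py), np.array(keep, dtype=int),
        pruned=True, window=curve.window, cube_id=curve.cube_id,
    )
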