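"""Labelled phantom cubes and exact curve fixtures for the three lesion classes.

The classifier consumes only ROI-curve statistics — the per-band
(window mean, window std) locus — so the phantoms control exactly that and
nothing else.  A class profile is a pair of per-band vectors (mu, sigma)
whose induced mean/std curve lands decisively on the right side of the
decision thresholds:

  benign     sigma flat and low (0.015-0.03) over a smoothly rising mu
  malignant  sigma elevated (0.08-0.29) with a moderate slope in mu
  melanoma   sigma steeply convex-increasing in mu (large totm)

Every generated profile is verified at construction by fitting its
noiseless curve and checking the decisive feature clears its threshold by
the requested margin.

Cubes realize a profile through a 7-periodic texture tile whose 49 values
have exactly zero mean and unit sample standard deviation: any aligned
7 x 7 window then reproduces (mu[k], sigma[k]) exactly, up to optional
per-voxel measurement noise and [0, 1] clipping.  A bright glare patch and
a dark shadow patch in the background corners (outside the sweep footprint)
pin the cube's global range so min-max normalization is the identity, and
the raw cube is emitted through the inverse calibration
raw = CI*(WI - DI) + DI with smooth synthetic references.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, ClassLabel
from .exceptions import GenerationError
from .features import compute_features
from .fitting import FitOptions, fit_quartic
from .io import RawCube, ReferenceSet, write_cube, write_references
from .roi import ROICurve, ROIWindow, prune

__all__ = [
    "ClassProfile",
    "PhantomSpec",
    "make_profile",
    "make_cube",
    "make_curve",
    "make_dataset",
    "save_dataset",
]

# default decisive-feature margins past the thresholds
MARGIN_TOTM = 0.5
MARGIN_MEAN = 0.02


@dataclass
class ClassProfile:
    """Per-band (mu, sigma) target for one lesion class, with verified margin."""

    label: ClassLabel
    mu: np.ndarray
    sigma: np.ndarray
    margin: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("profile must be finite")
        if self.mu.min() < 0 or self.mu.max() > 0.5 or self.sigma.min() < 0:
            raise ValueError("mu must lie in [0, 0.5] and sigma be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.mu.size


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, spectral axis, seed and noise level of one phantom capture."""

    side: int = 50
    bands: int = 125
    wavelength_range: tuple[float, float] = (450.0, 950.0)
    lesion_center: tuple[int, int] | None = None  # default: image center
    lesion_radius: float | None = None  # default: covers the sweep footprint
    seed: int = 0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.side < 39:
            raise ValueError("side must be >= 39 so the default sweep fits")
        if self.bands < 5:
            raise ValueError("at least 5 bands required")

    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.bands)


def _profile_features(profile: ClassProfile, cfg: ClassifierConfig):
    """Fit the noiseless (mu, sigma) curve and return its features."""
    curve = ROICurve(x=profile.mu, y=profile.sigma,
                     window=ROIWindow(center=(0, 0)), cube_id="profile")
    fit = fit_quartic(prune(curve), FitOptions())
    return compute_features(fit, prune(curve), a=cfg.a, b=cfg.b)


def _draw_profile(label: ClassLabel, rng: np.random.Generator, bands: int) -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(0.0, 1.0, bands)
    if label is ClassLabel.MELANOMA:
        lo, hi = rng.uniform(0.04, 0.06), rng.uniform(0.27, 0.31)
        mu = lo + (hi - lo) * u
        sigma = rng.uniform(0.015, 0.025) + rng.uniform(0.29, 0.32) * u**2
    elif label is ClassLabel.MALIGNANT:
        lo, hi = rng.uniform(0.09, 0.13), rng.uniform(0.32, 0.38)
        mu = lo + (hi - lo) * u
        sigma = rng.uniform(0.08, 0.11) + rng.uniform(0.10, 0.18) * u
    elif label is ClassLabel.BENIGN:
        lo, hi = rng.uniform(0.08, 0.12), rng.uniform(0.30, 0.38)
        mu = lo + (hi - lo) * u
        sigma = rng.uniform(0.018, 0.026) + rng.uniform(-0.004, 0.008) * u
    else:  # pragma: no cover
        raise ValueError(f"unknown label {label}")
    return mu, sigma


def make_profile(
    label: ClassLabel,
    rng: np.random.Generator | int | None = None,
    bands: int = 125,
    margin: float | None = None,
    cfg: ClassifierConfig | None = None,
    max_attempts: int = 20,
) -> ClassProfile:
    """Draw a class profile and verify its decisive-feature margin.

    The noiseless (mu, sigma) curve is fitted and the class's decisive
    feature must clear its threshold by ``margin`` (defaults: 0.5 on totm
    for melanoma, 0.02 on mean/mabdf otherwise); non-decisive thresholds
    must stay safely un-triggered.  Failing draws are resampled up to
    ``max_attempts`` times before raising GenerationError.
    """
    rng = np.random.default_rng(rng)
    cfg = cfg or ClassifierConfig()
    if margin is None:
        margin = MARGIN_TOTM if label is ClassLabel.MELANOMA else MARGIN_MEAN
    tile = _texture_tile()
    t_lo, t_hi = float(tile.min()), float(tile.max())
    for _ in range(max_attempts):
        mu, sigma = _draw_profile(label, rng, bands)
        # texture realizability: pixel values mu + sigma*t must stay in [0, 1]
        if (mu + t_lo * sigma).min() < 0 or (mu + t_hi * sigma).max() > 1:
            continue
        profile = ClassProfile(label=label, mu=mu, sigma=sigma, margin=margin)
        feats = _profile_features(profile, cfg)
        if label is ClassLabel.MELANOMA:
            ok = feats.totm >= cfg.c + margin
        elif label is ClassLabel.MALIGNANT:
            ok = feats.mean >= cfg.d + margin and feats.totm <= cfg.c - MARGIN_TOTM
        else:
            ok = (feats.mean <= cfg.g - margin and feats.mabdf <= cfg.f - margin
                  and feats.totm <= cfg.c - MARGIN_TOTM)
        if ok:
            return profile
    raise GenerationError(f"no valid {label.value} profile after {max_attempts} attempts")


def _texture_tile(side: int = 7) -> np.ndarray:
    """side x side bimodal tile with exact mean 0 and sample (ddof=1) std 1.

    Two levels emulate a pigment network: a darker majority phase and a
    lighter minority phase.  The levels are bounded (about -0.79 and
    +1.24), so mu + sigma*t stays inside [0, 1] for every class profile —
    a symmetric (e.g. Gaussian) texture would clip at 0 on the high-sigma
    melanoma bands and flatten the realized curves.
    """
    n = side * side
    n_dark = 30  # counts chosen so the exact-moment solution stays bounded
    n_light = n - n_dark
    t_light = math.sqrt((n - 1) * n_dark / (n_light * n))
    t_dark = -n_light / n_dark * t_light
    q = np.array([t_dark] * n_dark + [t_light] * n_light)
    # fixed shuffle so the texture is not a visible stripe; any arrangement
    # yields identical window statistics because the tile is window-periodic
    perm = np.random.default_rng(7).permutation(n)
    return q[perm].reshape(side, side)


def _default_radius(spec: PhantomSpec, footprint: tuple[int, int] = (12, 37)) -> float:
    cr, cc = spec.lesion_center or (spec.side // 2, spec.side // 2)
    lo, hi = footprint
    return max(math.hypot(cr - r, cc - c) for r in (lo, hi) for c in (lo, hi)) + 0.5


def make_cube(
    profile: ClassProfile,
    spec: PhantomSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RawCube, ReferenceSet, ClassLabel]:
    """Realize a profile as a raw cube plus references (see module docstring).

    ``calibrate`` applied to the output recovers the clean reflectance cube
    up to clipping, and the subsequent global normalization is pinned to
    the identity by the corner glare/shadow patches.
    """
    spec = spec or PhantomSpec()
    if profile.n_bands != spec.bands:
        raise ValueError(f"profile has {profile.n_bands} bands, spec expects {spec.bands}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    side, bands = spec.side, spec.bands
    center = spec.lesion_center or (side // 2, side // 2)
    radius = spec.lesion_radius if spec.lesion_radius is not None else _default_radius(spec)

    rr, cc = np.ogrid[:side, :side]
    lesion = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    if not lesion[center[0], center[1]]:
        warnings.warn("lesion disk does not cover the sweep region center", stacklevel=2)

    tile = _texture_tile()
    texture = np.tile(tile, (side // 7 + 1, side // 7 + 1))[:side, :side]

    clean = np.empty((side, side, bands))
    clean[:] = 0.05 + 0.005 * texture[:, :, None]  # faintly textured skin background
    clean[lesion] = profile.mu[None, :] + texture[lesion][:, None] * profile.sigma[None, :]
    if spec.noise_sd > 0:
        clean += spec.noise_sd * rng.standard_normal(clean.shape)
    clean = np.clip(clean, 0.0, 1.0)
    # glare and shadow patches outside the sweep footprint pin the global range
    clean[1:4, 1:4, :] = 1.0
    clean[side - 4 : side - 1, side - 4 : side - 1, :] = 0.0

    ii = np.arange(side)[:, None] / side
    jj = np.arange(side)[None, :] / side
    white = 0.85 + 0.05 * ii + 0.05 * jj  # smooth illumination falloff
    dark = 0.02 + 0.005 * ii + np.zeros_like(jj)
    raw = clean * (white[:, :, None] - dark[:, :, None]) + dark[:, :, None]

    cube = RawCube(data=raw, wavelengths=spec.wavelengths(),
                   id=f"SYN-{profile.label.value[:3].upper()}-{spec.seed}")
    return cube, ReferenceSet(white=white, dark=dark), profile.label


def make_curve(
    label: ClassLabel,
    margin: float | None = None,
    rng: np.random.Generator | int | None = None,
    bands: int = 125,
) -> ROICurve:
    """Exact curve-space fixture: the class profile itself, no sampling noise."""
    profile = make_profile(label, rng=rng, bands=bands, margin=margin)
    return ROICurve(x=profile.mu, y=profile.sigma,
                    window=ROIWindow(center=(25, 25)),
                    cube_id=f"EXACT-{label.value[:3].upper()}")


def make_dataset(
    n_per_class: int = 10,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[RawCube, ReferenceSet, ClassLabel]]:
    """Balanced, seeded list of (raw cube, references, truth label).

    A pure function of its arguments: the same (n_per_class, template,
    seed) always yields bit-identical cubes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec_template = spec_template or PhantomSpec()
    children = np.random.SeedSequence(seed).spawn(3 * n_per_class)
    out = []
    labels = [ClassLabel.MELANOMA, ClassLabel.MALIGNANT, ClassLabel.BENIGN]
    for i, label in enumerate(lab for lab in labels for _ in range(n_per_class)):
        rng = np.random.default_rng(children[i])
        profile = make_profile(label, rng=rng, bands=spec_template.bands)
        sub_seed = int(children[i].generate_state(1)[0] % 2**31)
        spec = replace(spec_template, seed=sub_seed)
        cube, refs, _ = make_cube(profile, spec, rng=rng)
        cube.id = f"SYN-{label.value[:3].upper()}-{i:03d}"
        out.append((cube, refs, label))
    return out


def save_dataset(
    dataset: list[tuple[RawCube, ReferenceSet, ClassLabel]],
    out_dir: str | Path,
) -> Path:
    """Write cubes, references and truth.csv; returns the truth table path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cube, refs, label in dataset:
        write_cube(cube, out / f"{cube.id}.npz")
        write_references(refs, out / f"{cube.id}.refs.npz")
        rows.append({"cube_id": cube.id, "label": label.value})
    truth_path = out / "truth.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    return truth_path
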