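"""Cube data model, white/dark reference calibration, normalization and file I/O.

A hyperspectral dermoscopy capture is a small reflectance cube: two spatial
axes (50 x 50 pixels for the target instrument) by one spectral axis
(125 bands spanning 450-950 nm).  Raw sensor counts are converted to
reflectance with the standard flat-field equation

    CI = (RI - DI) / (WI - DI)

where RI is the raw cube, WI the white-tile reference and DI the
closed-shutter dark reference, and then min-max normalized to [0, 1] per
cube so that downstream curve features are comparable across captures taken
under different illumination.

Two on-disk formats are supported: ENVI header + raw binary pairs (for
interoperability with spectral imaging tools) and a single-file NumPy
``.npz`` container (the internal format; bit-exact round trips).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .exceptions import (
    DataQualityError,
    DegenerateReferenceError,
    DimensionError,
    FormatError,
)

__all__ = [
    "RawCube",
    "ReferenceSet",
    "HSICube",
    "calibrate",
    "normalize",
    "read_cube",
    "write_cube",
    "read_references",
    "write_references",
]

Provenance = Literal["raw", "calibrated", "normalized", "synthetic"]


def _check_axes(data: np.ndarray, wavelengths: np.ndarray) -> None:
    if data.ndim != 3:
        raise DimensionError(f"cube data must be 3-D (rows, cols, bands); got shape {data.shape}")
    if data.shape[2] != wavelengths.shape[0]:
        raise DimensionError(
            f"{data.shape[2]} bands but {wavelengths.shape[0]} wavelength entries"
        )
    if not np.all(np.isfinite(wavelengths)) or np.any(np.diff(wavelengths) <= 0):
        raise DataQualityError("wavelengths must be finite and strictly increasing")
    if not np.all(np.isfinite(data)):
        raise DataQualityError("cube contains NaN or Inf")


@dataclass
class RawCube:
    """Uncalibrated sensor counts straight from the camera.

    Attributes
    ----------
    data : ndarray, shape (rows, cols, bands)
        Nonnegative intensity counts.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly increasing.
    id : str
        Capture identifier.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        _check_axes(self.data, self.wavelengths)
        if np.any(self.data < 0):
            raise DataQualityError("raw intensities must be nonnegative")


@dataclass
class ReferenceSet:
    """White-tile and dark (closed shutter) reference images.

    Each may be 2-D (one value per pixel, broadcast over bands) or 3-D
    with the cube's full shape.  The white reference must exceed the dark
    reference everywhere, otherwise the calibration denominator vanishes.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise DimensionError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )
        if self.white.ndim not in (2, 3):
            raise DimensionError("reference images must be 2-D or 3-D")
        if not (np.all(np.isfinite(self.white)) and np.all(np.isfinite(self.dark))):
            raise DataQualityError("reference images contain NaN or Inf")
        bad = self.white <= self.dark
        if np.any(bad):
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise DegenerateReferenceError(
                f"white <= dark at pixel {idx}: calibration denominator is not positive"
            )


@dataclass
class HSICube:
    """Calibrated (and possibly normalized) reflectance cube with values in [0, 1]."""

    data: np.ndarray
    wavelengths: np.ndarray
    id: str = ""
    provenance: Provenance = "calibrated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        _check_axes(self.data, self.wavelengths)
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise DataQualityError(
                f"reflectance outside [0, 1]: range [{self.data.min()}, {self.data.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _broadcast_ref(ref: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if ref.ndim == 2:
        if ref.shape != shape[:2]:
            raise DimensionError(f"reference spatial shape {ref.shape} != cube {shape[:2]}")
        return ref[:, :, None]
    if ref.shape != shape:
        raise DimensionError(f"reference shape {ref.shape} != cube {shape}")
    return ref


def calibrate(raw: RawCube, refs: ReferenceSet) -> HSICube:
    """Flat-field the raw cube against white and dark references.

    Computes ``(RI - DI) / (WI - DI)`` elementwise and clips the result to
    [0, 1]: sensor noise can push counts below the dark level (negative
    reflectance is unphysical) and specular glints above the 99%-reflective
    white tile.

    Raises
    ------
    DimensionError
        If the reference shapes are not broadcastable to the cube.
    DegenerateReferenceError
        If white == dark anywhere (raised when the ReferenceSet is built).
    """
    wi = _broadcast_ref(refs.white, raw.data.shape)
    di = _broadcast_ref(refs.dark, raw.data.shape)
    ci = (raw.data - di) / (wi - di)
    ci = np.clip(ci, 0.0, 1.0)
    return HSICube(data=ci, wavelengths=raw.wavelengths.copy(), id=raw.id, provenance="calibrated")


def normalize(cube: HSICube) -> HSICube:
    """Global per-cube min-max rescale to [0, 1].

    The rescale is global (one min and max over the whole cube, not per
    band) so relative magnitudes across bands — which the curve features
    depend on — are preserved.  A constant cube maps to all zeros.
    """
    data = cube.data
    if not np.all(np.isfinite(data)):
        raise DataQualityError("cube contains NaN or Inf")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return HSICube(data=out, wavelengths=cube.wavelengths.copy(), id=cube.id, provenance="normalized")


# ---------------------------------------------------------------------------
# File I/O: ENVI header+raw pairs and the npz portable container
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _envi_paths(path: Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".raw")
    return path.with_suffix(path.suffix + ".hdr") if path.suffix else Path(str(path) + ".hdr"), path


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic line")
    # join {...} blocks onto one logical line before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _write_envi(cube: RawCube | HSICube, path: Path, interleave: str = "bsq") -> None:
    hdr_path, raw_path = _envi_paths(path)
    data = cube.data.astype(np.float32)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        arr = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        arr = np.transpose(data, (0, 2, 1))
    elif interleave == "bip":
        arr = data
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    provenance = getattr(cube, "provenance", "raw")
    header = (
        "ENVI\n"
        f"description = {{hscurve cube id={cube.id} provenance={provenance}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[arr.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header)
    arr.tofile(raw_path)


def _read_envi(path: Path) -> RawCube | HSICube:
    hdr_path, raw_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    for key in ("samples", "lines", "bands", "wavelength"):
        if key not in fields:
            raise FormatError(f"ENVI header missing required field {key!r}")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    dtype = _ENVI_DTYPES.get(int(fields.get("data type", "4")))
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {fields['data type']}")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise FormatError(f"{bands} bands but {wavelengths.size} wavelength entries in header")
    interleave = fields.get("interleave", "bsq").lower()
    arr = np.fromfile(raw_path, dtype=dtype)
    if arr.size != rows * cols * bands:
        raise FormatError(f"raw file has {arr.size} values, expected {rows * cols * bands}")
    if interleave == "bsq":
        data = np.transpose(arr.reshape(bands, rows, cols), (1, 2, 0))
    elif interleave == "bil":
        data = np.transpose(arr.reshape(rows, bands, cols), (0, 2, 1))
    elif interleave == "bip":
        data = arr.reshape(rows, cols, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    data = data.astype(float)
    cube_id, provenance = "", "raw"
    m = re.search(r"id=(\S*)\s+provenance=(\w+)", fields.get("description", ""))
    if m:
        cube_id, provenance = m.group(1), m.group(2)
    if provenance == "raw":
        return RawCube(data=data, wavelengths=wavelengths, id=cube_id)
    return HSICube(data=data, wavelengths=wavelengths, id=cube_id, provenance=provenance)  # type: ignore[arg-type]


def write_cube(cube: RawCube | HSICube, path: str | Path, format: str = "npz", **kw) -> None:
    """Write a cube to disk.

    ``format='npz'`` stores float64 data, wavelengths, id and provenance in
    one file and round-trips bit-exactly; ``format='envi'`` writes a
    header+raw pair in float32 (accepts ``interleave`` in bsq/bil/bip).
    """
    path = Path(path)
    if format == "npz":
        np.savez(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            id=np.array(cube.id),
            provenance=np.array(getattr(cube, "provenance", "raw")),
        )
    elif format == "envi":
        _write_envi(cube, path, **kw)
    else:
        raise FormatError(f"unknown cube format {format!r}")


def read_cube(path: str | Path, format: str | None = None) -> RawCube | HSICube:
    """Read a cube written by :func:`write_cube`.

    The format is inferred from the extension when not given.  Returns a
    :class:`RawCube` when provenance is ``raw`` and an :class:`HSICube`
    otherwise.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "envi"
    if format == "envi":
        return _read_envi(path)
    if format != "npz":
        raise FormatError(f"unknown cube format {format!r}")
    with np.load(path) as z:
        for key in ("data", "wavelengths", "id", "provenance"):
            if key not in z:
                raise FormatError(f"container missing field {key!r}")
        data, wavelengths = z["data"], z["wavelengths"]
        cube_id, provenance = str(z["id"]), str(z["provenance"])
    if provenance == "raw":
        return RawCube(data=data, wavelengths=wavelengths, id=cube_id)
    return HSICube(data=data, wavelengths=wavelengths, id=cube_id, provenance=provenance)  # type: ignore[arg-type]


def write_references(refs: ReferenceSet, path: str | Path) -> None:
    np.savez(Path(path), white=refs.white, dark=refs.dark)


def read_references(path: str | Path) -> ReferenceSet:
    with np.load(Path(path)) as z:
        if "white" not in z or "dark" not in z:
            raise FormatError("reference container must hold 'white' and 'dark'")
        return ReferenceSet(white=z["white"], dark=z["dark"])
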