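"""Hyperspectral cube data model and on-disk formats.

A capture consists of three co-registered cubes — the tissue image ``It``,
a white-reference image ``Iw`` and a dark-signal image ``Id`` — plus, for
labelled samples, a 2D binary tumor mask traced from histology.

The canonical in-memory layout is ``(row, column, band)`` with row 0 at the
image top; every other module in the package assumes this ordering.

Supported on-disk dialects:

* ENVI header/binary pairs (``.hdr`` text header next to a raw binary file);
  float32 little-endian BSQ is the default written dialect, and BIL/BIP and
  the common integer/float data types are honoured on read.
* Multi-page TIFF, one page per band (via :mod:`tifffile`).
* NumPy ``.npz`` archives (``values`` + ``wavelengths_nm`` arrays).
* 8-bit single-channel PNG for label masks.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "SpectralAxis",
    "HSICube",
    "CaptureTriplet",
    "LabelMask",
    "FormatError",
    "IntegrityError",
    "read_cube",
    "write_cube",
    "read_label_mask",
    "write_label_mask",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """Header metadata and binary payload disagree."""


# --------------------------------------------------------------------------
# Data model
# --------------------------------------------------------------------------

def default_axis(band_count: int = 311, start_nm: float = 420.0,
                 step_nm: float = 1.0) -> "SpectralAxis":
    """Visible-range axis starting at 420 nm with a 1 nm step.

    The default 311 bands span 420-730 nm; band count is a free parameter
    because real instruments differ.
    """
    return SpectralAxis(start_nm + step_nm * np.arange(band_count))


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered band-center wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelengths_nm must be a 1-D non-empty vector")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths_nm must be finite")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def band_count(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (self.band_count == other.band_count
                and bool(np.allclose(self.wavelengths_nm, other.wavelengths_nm)))

    def __hash__(self) -> int:
        return hash(self.wavelengths_nm.tobytes())


CUBE_KINDS = ("raw_target", "white_reference", "dark_signal", "reflectance")


@dataclass
class HSICube:
    """A hyperspectral data cube, ``height x width x band_count``."""

    values: np.ndarray
    axis: SpectralAxis
    kind: str = "raw_target"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"cube values must be 3-D, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if v.shape[2] != self.axis.band_count:
            raise IntegrityError(
                f"cube has {v.shape[2]} bands but axis declares "
                f"{self.axis.band_count}")
        if not np.all(np.isfinite(v)):
            raise ValueError("cube values must be finite")
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"kind must be one of {CUBE_KINDS}, got {self.kind!r}")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def band_count(self) -> int:
        return self.values.shape[2]


@dataclass
class CaptureTriplet:
    """Target / white-reference / dark-signal cubes from one acquisition."""

    target: HSICube
    white: HSICube
    dark: HSICube

    def __post_init__(self) -> None:
        shapes = {self.target.shape, self.white.shape, self.dark.shape}
        if len(shapes) != 1:
            raise ValueError(
                "target, white and dark cubes must share dimensions; got "
                f"{self.target.shape}, {self.white.shape}, {self.dark.shape}")
        if not (self.target.axis == self.white.axis == self.dark.axis):
            raise ValueError("triplet cubes must share the spectral axis")


@dataclass
class LabelMask:
    """2-D binary tumor mask (1 = tumor) co-registered with a cube."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("label mask values must be 0/1")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


# --------------------------------------------------------------------------
# ENVI header/binary
# --------------------------------------------------------------------------

# ENVI "data type" codes <-> numpy dtypes (little-endian written by default).
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # Collapse { ... } blocks (possibly multi-line) before splitting on lines.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _envi_paths(path: str | Path) -> tuple[Path, Path]:
    """Return (header path, data path) for either given as input."""
    p = Path(path)
    if p.suffix.lower() == ".hdr":
        hdr = p
        dat = p.with_suffix(".img")
        if not dat.exists():
            dat = p.with_suffix("")
    else:
        dat = p
        hdr = p.with_suffix(".hdr")
        if not hdr.exists():
            hdr = Path(str(p) + ".hdr")
    return hdr, dat


def _read_envi(path: str | Path) -> HSICube:
    hdr_path, dat_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    raw = np.fromfile(dat_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise IntegrityError(
            f"ENVI payload holds {raw.size} values, header implies {expected}")
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wl = np.array([float(t) for t in wl_text.split(",") if t.strip()])
        if wl.size != bands:
            raise IntegrityError(
                f"header lists {wl.size} wavelengths for {bands} bands")
        axis = SpectralAxis(wl)
    else:
        axis = default_axis(bands)
    kind = fields.get("cube kind", "raw_target")
    if kind not in CUBE_KINDS:
        kind = "raw_target"
    return HSICube(np.ascontiguousarray(values), axis, kind)


def _write_envi(cube: HSICube, path: str | Path, dtype=np.float32) -> Path:
    dat_path = Path(path)
    if dat_path.suffix.lower() == ".hdr":
        dat_path = dat_path.with_suffix(".img")
    hdr_path = dat_path.with_suffix(".hdr")
    dtype = np.dtype(dtype).newbyteorder("<")
    base = np.dtype(dtype.str.lstrip("<>="))
    if base not in _DTYPE_CODES:
        raise FormatError(f"cannot write dtype {dtype} as ENVI")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:g}" for x in cube.axis.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[base]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n")
    cube.values.transpose(2, 0, 1).astype(dtype).tofile(dat_path)
    return dat_path


# --------------------------------------------------------------------------
# TIFF / NPZ
# --------------------------------------------------------------------------

def _read_tiff(path: str | Path) -> HSICube:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"expected band-paged TIFF, got shape {pages.shape}")
    values = np.ascontiguousarray(pages.transpose(1, 2, 0))
    meta = {}
    try:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
        if desc and desc.startswith("hsiseg:"):
            for item in desc[len("hsiseg:"):].split(";"):
                k, _, v = item.partition("=")
                meta[k] = v
    except Exception:
        pass
    if "wavelengths" in meta:
        wl = np.array([float(t) for t in meta["wavelengths"].split(",")])
        if wl.size != values.shape[2]:
            raise IntegrityError("TIFF wavelength tag does not match page count")
        axis = SpectralAxis(wl)
    else:
        axis = default_axis(values.shape[2])
    kind = meta.get("kind", "raw_target")
    return HSICube(values, axis, kind if kind in CUBE_KINDS else "raw_target")


def _write_tiff(cube: HSICube, path: str | Path) -> Path:
    wl = ",".join(f"{x:g}" for x in cube.axis.wavelengths_nm)
    desc = f"hsiseg:kind={cube.kind};wavelengths={wl}"
    tifffile.imwrite(path, cube.values.transpose(2, 0, 1).astype(np.float32),
                     photometric="minisblack", description=desc)
    return Path(path)


def _read_npz(path: str | Path) -> HSICube:
    with np.load(path) as archive:
        if "values" not in archive:
            raise FormatError("npz cube must contain a 'values' array")
        values = archive["values"]
        if "wavelengths_nm" in archive:
            axis = SpectralAxis(archive["wavelengths_nm"])
        else:
            axis = default_axis(values.shape[2])
        kind = str(archive["kind"]) if "kind" in archive else "raw_target"
    return HSICube(values, axis, kind if kind in CUBE_KINDS else "raw_target")


def _write_npz(cube: HSICube, path: str | Path) -> Path:
    np.savez(path, values=cube.values,
             wavelengths_nm=cube.axis.wavelengths_nm, kind=cube.kind)
    return Path(path)


# --------------------------------------------------------------------------
# Public read/write API
# --------------------------------------------------------------------------

_FORMATS = {"envi", "tiff", "npz"}


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".npz":
        return "npz"
    return "envi"


def read_cube(path: str | Path, format: str | None = None) -> HSICube:
    """Read a hyperspectral cube from disk.

    ``format`` is one of ``envi``, ``tiff`` or ``npz``; when omitted it is
    inferred from the file suffix (ENVI being the fall-through default).
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "tiff":
        return _read_tiff(path)
    return _read_npz(path)


def write_cube(cube: HSICube, path: str | Path, format: str | None = None,
               dtype=np.float32) -> Path:
    """Write a cube; the output round-trips through :func:`read_cube`."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    parent = Path(path).parent
    if parent and not parent.exists():
        raise IOError(f"directory {parent} does not exist")
    if fmt == "envi":
        return _write_envi(cube, path, dtype=dtype)
    if fmt == "tiff":
        return _write_tiff(cube, path)
    return _write_npz(cube, path)


def read_label_mask(path: str | Path) -> LabelMask:
    """Read a binary mask from a single-channel PNG (or .npy) raster.

    8-bit input is binarised at 0.5 of full scale (values >= 128 become 1).
    """
    p = Path(path)
    if p.suffix.lower() == ".npy":
        arr = np.load(p)
    else:
        img = Image.open(p)
        if img.mode not in ("L", "I", "I;16", "1"):
            raise FormatError(
                f"label mask must be single-channel, got mode {img.mode!r}")
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError("label mask raster must be 2-D single-channel")
    if arr.dtype == np.uint8:
        values = (arr >= 128).astype(np.uint8)
    else:
        values = (arr > 0.5).astype(np.uint8)
    return LabelMask(values, provenance=str(path))


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    p = Path(path)
    if p.suffix.lower() == ".npy":
        np.save(p, mask.values)
    else:
        Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(p)
    return p
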