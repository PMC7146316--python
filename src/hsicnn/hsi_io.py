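"""Readers and writers for hyperspectral scenes and their products.

Supported formats:

* ENVI cubes — a plain-text ``.hdr`` header next to a raw binary file, in
  any of the three standard interleaves (BSQ, BIL, BIP).
* MAT-style containers (as the public benchmark scenes are distributed) —
  read through :mod:`scipy.io`; the cube may sit under any variable name.
* Ground-truth label rasters — 2D integer arrays in MAT containers or
  plain CSV; label ``0`` marks unlabeled background.
* Classification maps — a paletted PNG for viewing plus a lossless CSV
  integer matrix.

Band indices are **1-based** at every public boundary, matching how
corrupted water-absorption bands are quoted for the benchmark scenes
(e.g. ``"108-112,154-167,224"``); arrays are 0-based internally.  The
parse/format layer is exactly where the convention switches.

Reflectance values are kept in their native sensor scale on load;
standardization is preprocessing, not I/O.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io
from PIL import Image

__all__ = [
    "HSICube",
    "GroundTruth",
    "BandRemovalSpec",
    "FormatError",
    "load_cube",
    "save_cube",
    "write_envi",
    "read_envi",
    "load_ground_truth",
    "save_ground_truth",
    "parse_band_removal",
    "save_classification_map",
    "load_label_matrix",
    "default_palette",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class HSICube:
    """A hyperspectral reflectance cube of shape (rows, cols, bands).

    ``band_ids`` carry the original 1-based sensor band numbers; after
    band removal the surviving entries keep their original ids, so a
    spectrum can always be traced back to physical bands.
    """

    values: np.ndarray
    band_ids: np.ndarray = None  # type: ignore[assignment]
    wavelengths_nm: Optional[np.ndarray] = None
    scene_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3D (rows, cols, bands), got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"cube dimensions must all be >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")
        if self.band_ids is None:
            self.band_ids = np.arange(1, self.values.shape[2] + 1)
        self.band_ids = np.asarray(self.band_ids, dtype=int)
        if self.band_ids.shape != (self.values.shape[2],):
            raise ValueError("band_ids length must equal the number of bands")
        if np.any(np.diff(self.band_ids) <= 0):
            raise ValueError("band_ids must be strictly increasing")
        if self.wavelengths_nm is not None:
            self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
            if self.wavelengths_nm.shape != (self.values.shape[2],):
                raise ValueError("wavelengths_nm length must equal the number of bands")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def spectra(self) -> np.ndarray:
        """All pixel spectra as a (rows*cols, bands) float matrix."""
        return self.values.reshape(-1, self.n_bands).astype(float)


@dataclass
class GroundTruth:
    """A per-pixel class label raster; 0 marks unlabeled background."""

    labels: np.ndarray
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"ground truth must be 2D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative (0 = unlabeled)")
        max_label = int(self.labels.max(initial=0))
        if self.class_names is None:
            self.class_names = [f"class-{i:02d}" for i in range(1, max_label + 1)]
        elif max_label > len(self.class_names):
            raise ValueError(
                f"label {max_label} exceeds the {len(self.class_names)} provided class names"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def labeled_pixels(self) -> np.ndarray:
        """All labeled pixels as an (n, 3) array of (row, col, label)."""
        rr, cc = np.nonzero(self.labels)
        return np.column_stack([rr, cc, self.labels[rr, cc]])


@dataclass(frozen=True)
class BandRemovalSpec:
    """A normalized set of 1-based inclusive band ranges to drop."""

    ranges: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        norm = _normalize_ranges(self.ranges)
        object.__setattr__(self, "ranges", norm)

    def indices(self) -> list[int]:
        """The removed band ids, sorted ascending (1-based)."""
        out: list[int] = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return out

    def __len__(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.ranges)

    def __str__(self) -> str:
        return ",".join(f"{lo}-{hi}" if hi > lo else f"{lo}" for lo, hi in self.ranges)


def _normalize_ranges(ranges: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    pairs = sorted((int(lo), int(hi)) for lo, hi in ranges)
    for lo, hi in pairs:
        if lo < 1:
            raise ValueError(f"band indices are 1-based; got {lo}")
        if hi < lo:
            raise ValueError(f"inverted range {lo}-{hi}")
    merged: list[tuple[int, int]] = []
    for lo, hi in pairs:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


def parse_band_removal(text: str) -> BandRemovalSpec:
    """Parse a band-removal string like ``"108-112,154-167,224"``.

    Comma-separated, 1-based inclusive ranges and singletons; whitespace
    is ignored; an empty string yields an empty spec.
    """
    text = text.strip()
    if not text:
        return BandRemovalSpec()
    ranges: list[tuple[int, int]] = []
    for token in text.split(","):
        token = token.strip()
        m = re.fullmatch(r"(\d+)(?:\s*-\s*(\d+))?", token)
        if m is None:
            raise ValueError(f"malformed band token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        ranges.append((lo, hi))
    return BandRemovalSpec(tuple(ranges))


# --------------------------------------------------------------------------
# ENVI header + raw binary
# --------------------------------------------------------------------------

# ENVI data-type codes <-> numpy dtypes
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _header_path(path: Path) -> Path:
    for cand in (Path(str(path) + ".hdr"), path.with_suffix(".hdr")):
        if cand.exists():
            return cand
    raise FormatError(f"no ENVI header found for {path} (tried '<file>.hdr' and '*.hdr')")


def _parse_envi_header(hdr_path: Path) -> dict[str, str]:
    text = hdr_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError(f"{hdr_path} is not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # brace-delimited values may span lines; collapse them first
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path: str | os.PathLike) -> HSICube:
    """Read an ENVI cube (header + raw binary) into row × col × band order."""
    path = Path(path)
    hdr = _parse_envi_header(_header_path(path))
    try:
        lines = int(hdr["lines"])
        samples = int(hdr["samples"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
        interleave = hdr.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"incomplete or corrupt ENVI header for {path}: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(hdr.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(hdr.get("header offset", "0"))
    raw = np.fromfile(path, dtype=dtype, offset=offset)
    if raw.size != lines * samples * bands:
        raise FormatError(
            f"{path}: expected {lines * samples * bands} values, found {raw.size}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    wavelengths = None
    if "wavelength" in hdr:
        inner = hdr["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(t) for t in inner.split(",") if t.strip()])
        if wavelengths.size != bands:
            wavelengths = None
    return HSICube(values.copy(), wavelengths_nm=wavelengths, scene_name=path.stem)


def write_envi(cube: HSICube, path: str | os.PathLike, interleave: str = "bsq") -> Path:
    """Write a cube as raw binary plus a ``<file>.hdr`` ENVI header."""
    path = Path(path)
    interleave = interleave.lower()
    values = np.ascontiguousarray(cube.values)
    if values.dtype not in _DTYPE_CODES:
        values = values.astype(np.float64)
    if interleave == "bsq":
        ordered = values.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = values.transpose(0, 2, 1)
    elif interleave == "bip":
        ordered = values
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(ordered).tofile(path)
    header = [
        "ENVI",
        f"description = {{{cube.scene_name or path.stem}}}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[values.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if cube.wavelengths_nm is not None:
        header.append("wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths_nm) + "}")
    Path(str(path) + ".hdr").write_text("\n".join(header) + "\n")
    return path


# --------------------------------------------------------------------------
# MAT-style containers
# --------------------------------------------------------------------------

def _mat_arrays(path: Path) -> dict[str, np.ndarray]:
    try:
        contents = scipy.io.loadmat(path)
    except Exception as exc:  # scipy raises a zoo of types for bad files
        raise FormatError(f"cannot read MAT container {path}: {exc}") from exc
    return {
        k: np.asarray(v)
        for k, v in contents.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
        and np.issubdtype(np.asarray(v).dtype, np.number)
    }


def _unique_array(path: Path, ndim: int, variable: Optional[str]) -> np.ndarray:
    arrays = _mat_arrays(path)
    if variable is not None:
        if variable not in arrays:
            raise FormatError(f"{path} has no numeric variable {variable!r}")
        return arrays[variable]
    matches = {k: v for k, v in arrays.items() if v.ndim == ndim}
    if len(matches) != 1:
        raise FormatError(
            f"{path} holds {len(matches)} {ndim}-D numeric arrays "
            f"({sorted(matches)}); pass an explicit variable name"
        )
    return next(iter(matches.values()))


def load_cube(
    path: str | os.PathLike,
    format: Optional[str] = None,
    variable: Optional[str] = None,
) -> HSICube:
    """Load a cube from ENVI or a MAT-style container.

    ``format`` is ``"envi"`` or ``"mat-array"``; when omitted it is
    inferred from the file suffix (``.mat`` → MAT, anything else → ENVI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mat-array" if path.suffix.lower() == ".mat" else "envi"
    if format == "envi":
        return read_envi(path)
    if format == "mat-array":
        arr = _unique_array(path, 3, variable)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array in {path}, got ndim={arr.ndim}")
        return HSICube(arr, scene_name=path.stem)
    raise ValueError(f"unknown cube format {format!r}")


def save_cube(
    cube: HSICube,
    path: str | os.PathLike,
    format: str = "envi",
    interleave: str = "bsq",
) -> Path:
    path = Path(path)
    if format == "envi":
        return write_envi(cube, path, interleave=interleave)
    if format == "mat-array":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.savemat(path, {"cube": cube.values})
        return path
    raise ValueError(f"unknown cube format {format!r}")


def load_ground_truth(
    path: str | os.PathLike,
    class_names: Optional[list[str]] = None,
    variable: Optional[str] = None,
) -> GroundTruth:
    """Load a 2D label raster from a MAT container or a CSV matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mat":
        arr = _unique_array(path, 2, variable)
    else:
        arr = load_label_matrix(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"ground truth must be 2D, got ndim={arr.ndim}")
    if arr.min(initial=0) < 0:
        raise ValueError("ground-truth labels must be non-negative")
    return GroundTruth(arr.astype(int), class_names=class_names)


def save_ground_truth(gt: GroundTruth, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, gt.labels, fmt="%d", delimiter=",")
    return path


# --------------------------------------------------------------------------
# Classification maps
# --------------------------------------------------------------------------

def default_palette(n_classes: int) -> list[tuple[int, int, int]]:
    """Black for unlabeled (0) plus ``n_classes`` distinct hues."""
    import colorsys

    palette = [(0, 0, 0)]
    for i in range(n_classes):
        h = i / max(n_classes, 1)
        s = 0.85 if i % 2 == 0 else 0.55
        v = 0.95 if i % 3 != 2 else 0.65
        r, g, b = colorsys.hsv_to_rgb(h, s, v)
        palette.append((int(round(r * 255)), int(round(g * 255)), int(round(b * 255))))
    return palette


def save_classification_map(
    labels: np.ndarray,
    palette: Sequence[tuple[int, int, int]],
    path: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write a label raster as a paletted PNG plus a lossless CSV matrix.

    Returns ``(png_path, csv_path)``.  Label 0 renders as the first
    palette entry (conventionally black).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("classification map must be 2D")
    max_label = int(labels.max(initial=0))
    if max_label >= len(palette):
        raise ValueError(f"label {max_label} has no palette entry (palette size {len(palette)})")
    if max_label > 255:
        raise ValueError("paletted PNG supports at most 256 classes")
    png_path = Path(path)
    if png_path.suffix.lower() != ".png":
        png_path = png_path.with_suffix(".png")
    png_path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = [c for rgb in palette for c in rgb]
    flat += [0] * (768 - len(flat))
    img.putpalette(flat)
    img.save(png_path)
    csv_path = png_path.with_suffix(".csv")
    np.savetxt(csv_path, labels, fmt="%d", delimiter=",")
    return png_path, csv_path


def load_label_matrix(path: str | os.PathLike) -> np.ndarray:
    """Read a CSV integer label matrix back as a 2D int array."""
    arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    out = arr.astype(int)
    if not np.array_equal(out, arr):
        raise ValueError(f"{path} contains non-integer labels")
    return out
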