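"""Hyperspectral cube containers and I/O.

The imaging unit throughout the package is an absorbance cube: an H×W raster of
infrared spectra on a shared wavenumber axis (cm⁻¹).  Cubes are exchanged as
ENVI files (a plain-text ``.hdr`` plus a raw binary block, interleave bsq/bil/
bip, IEEE float32/float64) — the de-facto exchange format for FT-IR imaging.
Cohort metadata travels as CSV with a fixed column schema.

Conventions: row-major, (row, col) with origin top-left, 0-based; the
wavenumber axis is stored ascending (files with descending wavelength lists are
flipped on read and the flip is logged); absorbance is held as float64
in memory regardless of on-disk type.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "ecmir-cohort-v1"

#: Fixed cohort-table column schema (one row per patient).
COHORT_COLUMNS = [
    "patient_id",
    "ecm_class",        # "ECM3" / "non-ECM3" (gene-expression label)
    "grade",            # "I-II" / "III"
    "size_class",       # "<2cm" / ">=2cm"
    "nodal_status",     # "N0" / "N+"
    "er_status",        # "negative" / "positive"
    "pgr_status",
    "her2_status",
    "mean_log2_expr",   # mean log2 expression of the 58-gene ECM3 cluster
    "survival_months",
    "event",            # 1 = event observed, 0 = censored
]


class EnviFormatError(ValueError):
    """Malformed or inconsistent ENVI header/data pair."""


class AxisMismatchError(ValueError):
    """Cubes with incompatible wavenumber axes were combined."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, uniformly spaced wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavenumber axis needs at least 2 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("wavenumber axis must be uniformly spaced")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def index_nearest(self, wavenumber: float) -> int:
        """Index of the band nearest ``wavenumber``; ties go to the lower band."""
        d = np.abs(self.values - wavenumber)
        m = d.min()
        return int(np.nonzero(np.isclose(d, m, rtol=0.0, atol=1e-12))[0][0])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.values >= lo) & (self.values <= hi)

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "WavenumberAxis":
        n_steps = (hi - lo) / step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(f"step {step} does not divide range [{lo}, {hi}]")
        return cls(lo + step * np.arange(int(round(n_steps)) + 1))


@dataclass
class HyperspectralCube:
    """H×W×B absorbance raster with a wavenumber axis and validity mask."""

    data: np.ndarray                       # (H, W, B) float64, a.u.
    axis: WavenumberAxis
    pixel_size: float = 6.25               # µm
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H×W×B")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {self.data.shape[2]} != axis length {len(self.axis)}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.data.shape[:2]:
            raise ValueError("valid_mask shape must be (H, W)")
        if not np.all(np.isfinite(self.data[self.valid_mask])):
            raise ValueError("absorbance must be finite on valid pixels")

    @property
    def shape(self):
        return self.data.shape

    def flat_spectra(self) -> np.ndarray:
        """All pixel spectra as an (H·W, B) view-copy, row-major pixel order."""
        H, W, B = self.data.shape
        return self.data.reshape(H * W, B)


# --------------------------------------------------------------------------
# ENVI read / write
# --------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header grammar."""
    fields: dict[str, str] = {}
    # collapse brace blocks (may span lines)
    text = re.sub(r"^ENVI\s*", "", text.strip())
    pos = 0
    while pos < len(text):
        m = re.match(r"\s*([\w ]+?)\s*=\s*", text[pos:])
        if not m:
            break
        key = m.group(1).strip().lower()
        pos += m.end()
        if pos < len(text) and text[pos] == "{":
            end = text.find("}", pos)
            if end < 0:
                raise EnviFormatError(f"unterminated brace block for '{key}'")
            fields[key] = text[pos + 1 : end].strip()
            pos = end + 1
        else:
            eol = text.find("\n", pos)
            eol = len(text) if eol < 0 else eol
            fields[key] = text[pos:eol].strip()
            pos = eol + 1
    return fields


def _data_path_for(header_path: Path) -> Path:
    base = header_path.with_suffix("")
    for cand in (base, base.with_suffix(".dat"), base.with_suffix(".raw"),
                 base.with_suffix(".img")):
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no data file found next to {header_path}")


def read_envi(header_path) -> HyperspectralCube:
    """Read an ENVI header + raw binary pair into a :class:`HyperspectralCube`.

    Supports bsq/bil/bip interleaves and float32/float64 (ENVI data types 4
    and 5).  A descending wavelength list is flipped to ascending.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    try:
        samples = int(fields["samples"])   # W
        lines = int(fields["lines"])       # H
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc

    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength block")
    wavelengths = np.array(
        [float(t) for t in re.split(r"[\s,]+", fields["wavelength"]) if t]
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"bands={bands} but wavelength list has {wavelengths.size} entries"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave '{interleave}'")

    raw = np.fromfile(_data_path_for(header_path), dtype=_ENVI_DTYPES[dtype_code])
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"data file has {raw.size} values, expected {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    if wavelengths[0] > wavelengths[-1]:
        logger.info("read_envi: descending wavelength list in %s flipped to "
                    "ascending", header_path.name)
        wavelengths = wavelengths[::-1]
        data = data[:, :, ::-1]

    pixel_size = float(fields.get("pixel size", 6.25))
    return HyperspectralCube(
        data=np.ascontiguousarray(data, dtype=np.float64),
        axis=WavenumberAxis(wavelengths),
        pixel_size=pixel_size,
    )


def write_envi(cube: HyperspectralCube, path, interleave: str = "bsq",
               dtype: str = "float64") -> Path:
    """Write ``cube`` as ``<path>.hdr`` + ``<path>.dat``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _ENVI_CODES:
        raise ValueError("only float32/float64 cubes are written")

    path = Path(path).with_suffix("")
    H, W, B = cube.data.shape
    if interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = cube.data.transpose(0, 2, 1)
    else:
        out = cube.data
    out.astype(np_dtype.newbyteorder("<")).tofile(path.with_suffix(".dat"))

    wl = "\n".join(f"  {v:.6f}" for v in cube.axis.values)
    header = (
        "ENVI\n"
        f"description = {{{SCHEMA_VERSION}}}\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size = {cube.pixel_size}\n"
        "wavelength units = Wavenumber (cm-1)\n"
        f"wavelength = {{\n{wl}\n}}\n"
    )
    hdr = path.with_suffix(".hdr")
    hdr.write_text(header)
    return hdr


# --------------------------------------------------------------------------
# Tile stitching
# --------------------------------------------------------------------------

def stitch_tiles(tiles: list[HyperspectralCube],
                 grid: tuple[int, int]) -> HyperspectralCube:
    """Butt-joint tiles (row-major order) into one cube; no blending or overlap.

    All tiles must share the wavenumber axis and pixel size; tile heights must
    agree within a grid row and widths within a grid column.
    """
    rows, cols = grid
    if rows * cols != len(tiles):
        raise ValueError(f"grid {grid} needs {rows * cols} tiles, got {len(tiles)}")
    ref = tiles[0]
    for t in tiles[1:]:
        if len(t.axis) != len(ref.axis) or not np.array_equal(
                t.axis.values, ref.axis.values):
            raise AxisMismatchError("tiles have different wavenumber axes")
        if t.pixel_size != ref.pixel_size:
            raise AxisMismatchError("tiles have different pixel sizes")

    mesh = [[tiles[i * cols + j] for j in range(cols)] for i in range(rows)]
    for i in range(rows):
        hs = {mesh[i][j].shape[0] for j in range(cols)}
        if len(hs) != 1:
            raise ValueError(f"inconsistent tile heights in grid row {i}")
    for j in range(cols):
        ws = {mesh[i][j].shape[1] for i in range(rows)}
        if len(ws) != 1:
            raise ValueError(f"inconsistent tile widths in grid column {j}")

    data = np.concatenate(
        [np.concatenate([m.data for m in row], axis=1) for row in mesh],
        axis=0)
    mask = np.concatenate(
        [np.concatenate([m.valid_mask for m in row], axis=1) for row in mesh],
        axis=0)
    return HyperspectralCube(data=data, axis=ref.axis,
                             pixel_size=ref.pixel_size, valid_mask=mask)


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

def write_cohort_table(table: pd.DataFrame, path) -> Path:
    """Write a cohort table as CSV with a schema-version comment line."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    # round_trip parsing keeps saved floats bit-identical to the written ones
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    if table["patient_id"].duplicated().any():
        raise ValueError("patient_id values must be unique")
    return table
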