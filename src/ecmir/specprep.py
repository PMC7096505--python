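"""Per-pixel spectral preprocessing.

Fixed pipeline order (each step optional by configuration, order logged):
baseline correction → normalization → (SNR gate) → Savitzky-Golay smoothing →
training-window subsetting → out-of-range cleaning.  All steps operate on
single spectra or on (N, B) stacks of pixel spectra sharing one axis.

Defaults: rubberband (lower convex hull) baseline over the full measured
range, amide-I peak normalization (value at the band nearest 1656 cm⁻¹ scaled
to 1), 9-point quadratic Savitzky-Golay, training window 872–1320 cm⁻¹
inclusive, cleaning bounds (−1, 2) absorbance units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .hyperio import HyperspectralCube, WavenumberAxis

try:  # JIT path for per-pixel hulls on whole cubes; pure-python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

logger = logging.getLogger(__name__)

AMIDE_I = 1656.0
SNR_NOISE_BAND = 1826.0


class DegenerateSpectrumError(ValueError):
    """Normalizer is zero/non-positive; the pixel must be excluded downstream."""


class RangeError(ValueError):
    """Requested spectral range does not intersect the axis."""


@dataclass(frozen=True)
class PreprocessConfig:
    train_range: tuple[float, float] = (872.0, 1320.0)
    snr_signal_band: float = AMIDE_I
    snr_noise_band: float = SNR_NOISE_BAND
    savgol_window: int = 9
    savgol_order: int = 2
    clean_max: float = 2.0
    clean_min: float = -1.0
    baseline_method: str = "rubberband"   # rubberband | anchor_linear | none
    norm_method: str = "amide_I_peak"     # amide_I_peak | unit_vector | none
    anchor_wavenumbers: tuple[float, float] = (750.0, 2000.0)
    background_floor: float = 0.1         # raw amide-I a.u. below which = background

    def __post_init__(self):
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if self.clean_min >= self.clean_max:
            raise ValueError("clean_min must be < clean_max")
        if self.baseline_method not in ("rubberband", "anchor_linear", "none"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.norm_method not in ("amide_I_peak", "unit_vector", "none"):
            raise ValueError(f"unknown normalization {self.norm_method!r}")

    def manifest(self) -> dict:
        """Provenance record of every preprocessing parameter."""
        return {
            "pipeline_order": ["baseline", "normalize", "snr_gate", "smooth",
                               "subset", "clean"],
            "baseline_method": self.baseline_method,
            "norm_method": self.norm_method,
            "savgol_window": self.savgol_window,
            "savgol_order": self.savgol_order,
            "train_range": list(self.train_range),
            "clean_bounds": [self.clean_min, self.clean_max],
            "snr_bands": [self.snr_signal_band, self.snr_noise_band],
            "background_floor": self.background_floor,
        }


# --------------------------------------------------------------------------
# Baseline correction
# --------------------------------------------------------------------------

def _lower_hull_monotone(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain lower hull of one spectrum, evaluated at every x."""
    pts: list[int] = []
    for i in range(x.size):
        while len(pts) >= 2:
            i1, i2 = pts[-2], pts[-1]
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                pts.pop()
            else:
                break
        pts.append(i)
    idx = np.array(pts)
    return np.interp(x, x[idx], y[idx])


def _hull_envelopes_python(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    out = np.empty_like(Y)
    for i in range(Y.shape[0]):
        out[i] = _lower_hull_monotone(x, Y[i])
    return out


if _njit is not None:
    @_njit(cache=False)
    def _hull_envelopes_jit(x, Y):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        out = np.empty_like(Y)
        stack = np.empty(n, np.int64)
        for r in range(Y.shape[0]):
            y = Y[r]
            k = 0
            for i in range(n):
                while k >= 2:
                    i1 = stack[k - 2]
                    i2 = stack[k - 1]
                    cross = ((x[i2] - x[i1]) * (y[i] - y[i1])
                             - (y[i2] - y[i1]) * (x[i] - x[i1]))
                    if cross <= 0:
                        k -= 1
                    else:
                        break
                stack[k] = i
                k += 1
            seg = 0
            for i in range(n):
                while seg < k - 2 and x[stack[seg + 1]] < x[i]:
                    seg += 1
                i1 = stack[seg]
                i2 = stack[seg + 1]
                t = (x[i] - x[i1]) / (x[i2] - x[i1])
                out[r, i] = y[i1] + t * (y[i2] - y[i1])
        return out


def _hull_envelopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if _njit is not None:
        return _hull_envelopes_jit(np.ascontiguousarray(x),
                                   np.ascontiguousarray(Y))
    return _hull_envelopes_python(x, Y)


def baseline_correct(spectrum: np.ndarray, axis: WavenumberAxis,
                     method: str = "rubberband",
                     anchors: tuple[float, float] | None = None) -> np.ndarray:
    """Subtract a baseline estimate; vectorized over an (N, B) stack.

    rubberband: lower convex-hull envelope (touches the spectrum at hull
    points, including both endpoints; residual ≥ 0 up to round-off).
    anchor_linear: straight line through the two configured anchor bands.
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum must be finite")
    single = y.ndim == 1
    Y = y[None, :] if single else y
    x = axis.values
    if Y.shape[1] != x.size:
        raise ValueError("spectrum length does not match axis")

    if method == "none":
        out = Y.copy()
    elif method == "rubberband":
        out = Y - _hull_envelopes(x, Y)
    elif method == "anchor_linear":
        a0, a1 = anchors if anchors is not None else (x[0], x[-1])
        if not (x[0] <= a0 <= x[-1]) or not (x[0] <= a1 <= x[-1]):
            raise ValueError("anchor wavenumbers outside the axis")
        i0, i1 = axis.index_nearest(a0), axis.index_nearest(a1)
        if i0 == i1:
            raise ValueError("anchor wavenumbers resolve to the same band")
        slope = (Y[:, i1] - Y[:, i0]) / (x[i1] - x[i0])
        line = Y[:, i0][:, None] + slope[:, None] * (x - x[i0])[None, :]
        out = Y - line
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return out[0] if single else out


# --------------------------------------------------------------------------
# Normalization, SNR, smoothing
# --------------------------------------------------------------------------

def normalize(spectrum: np.ndarray, axis: WavenumberAxis,
              method: str = "amide_I_peak",
              amide_band: float = AMIDE_I) -> np.ndarray:
    """Scale-invariant normalization of a single spectrum.

    amide_I_peak divides by the intensity at the band nearest 1656 cm⁻¹;
    unit_vector divides by the Euclidean norm.  A non-positive normalizer
    raises :class:`DegenerateSpectrumError` (pixel to be flagged and excluded).
    """
    y = np.asarray(spectrum, dtype=float)
    if method == "none":
        return y.copy()
    if method == "amide_I_peak":
        norm = y[axis.index_nearest(amide_band)]
    elif method == "unit_vector":
        norm = float(np.linalg.norm(y))
    else:
        raise ValueError(f"unknown normalization {method!r}")
    if not norm > 0:
        raise DegenerateSpectrumError(f"normalizer {norm} is not positive")
    return y / norm


def compute_snr(spectrum: np.ndarray, axis: WavenumberAxis,
                signal_band: float = AMIDE_I,
                noise_band: float = SNR_NOISE_BAND) -> float:
    """Intensity ratio I(nearest 1656 cm⁻¹) / I(nearest 1826 cm⁻¹); no clipping."""
    y = np.asarray(spectrum, dtype=float)
    num = y[axis.index_nearest(signal_band)]
    den = y[axis.index_nearest(noise_band)]
    if den == 0:
        logger.warning("compute_snr: zero intensity in the noise band; SNR = inf")
        return float("inf") if num >= 0 else float("-inf")
    return float(num / den)


def savgol_smooth(spectrum: np.ndarray, window: int = 9, order: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along the band axis.

    Edges are handled by polynomial fits on the truncated end windows
    (no zero padding).  Works on 1-D spectra and (N, B) stacks.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    y = np.asarray(spectrum, dtype=float)
    if window > y.shape[-1]:
        raise ValueError("window longer than spectrum")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    return savgol_filter(y, window, order, axis=-1, mode="interp")


# --------------------------------------------------------------------------
# Subsetting and cleaning
# --------------------------------------------------------------------------

def subset_range(spectra: np.ndarray, axis: WavenumberAxis,
                 lo: float = 872.0, hi: float = 1320.0
                 ) -> tuple[np.ndarray, WavenumberAxis]:
    """Restrict to bands with lo ≤ ν ≤ hi (inclusive); returns (data, new axis)."""
    mask = axis.window_mask(lo, hi)
    if not mask.any():
        raise RangeError(f"[{lo}, {hi}] selects no bands on this axis")
    sel = np.asarray(spectra, dtype=float)[..., mask]
    vals = axis.values[mask]
    if vals.size == 1:
        # single-band result: keep a degenerate 2-point axis unnecessary;
        # return the raw value array with a 1-band pseudo-axis
        return sel, _SingleBandAxis(vals[0])
    return sel, WavenumberAxis(vals)


class _SingleBandAxis:
    """Degenerate one-band axis returned when a range selects a single band."""

    def __init__(self, value: float):
        self.values = np.array([value])

    def __len__(self):
        return 1


def subset_cube(cube: HyperspectralCube, lo: float = 872.0, hi: float = 1320.0
                ) -> HyperspectralCube:
    data, ax = subset_range(cube.data, cube.axis, lo, hi)
    return HyperspectralCube(data=data, axis=ax, pixel_size=cube.pixel_size,
                             valid_mask=cube.valid_mask.copy())


def clean_pixels(spectra: np.ndarray, clean_min: float = -1.0,
                 clean_max: float = 2.0) -> tuple[np.ndarray, dict]:
    """Drop pixels with any retained-band absorbance outside [clean_min, clean_max].

    Pure filter: surviving spectra are returned unchanged.  Returns the boolean
    keep mask and a rejection log with per-reason counts.
    """
    Y = np.atleast_2d(np.asarray(spectra, dtype=float))
    too_high = np.any(Y > clean_max, axis=1)
    too_low = np.any(Y < clean_min, axis=1)
    keep = ~(too_high | too_low)
    log = {
        "n_input": int(Y.shape[0]),
        "n_kept": int(keep.sum()),
        "n_removed_above_max": int(too_high.sum()),
        "n_removed_below_min": int(too_low.sum()),
    }
    if log["n_kept"] < log["n_input"]:
        logger.info("clean_pixels: removed %d/%d pixels (%d above %g, %d below %g)",
                    log["n_input"] - log["n_kept"], log["n_input"],
                    log["n_removed_above_max"], clean_max,
                    log["n_removed_below_min"], clean_min)
    return keep, log


# --------------------------------------------------------------------------
# Cube-level pipeline
# --------------------------------------------------------------------------

def preprocess_cube(cube: HyperspectralCube, config: PreprocessConfig
                    ) -> tuple[HyperspectralCube, dict]:
    """Baseline-correct, normalize and smooth every pixel of a cube.

    Pixels whose baseline-corrected amide-I intensity falls below
    ``background_floor`` are flagged invalid (background) and left
    unnormalized; everything else follows the fixed pipeline order.  Returns
    the processed cube and a manifest dict that also carries the raw amide-I
    image (needed for background gating downstream).
    """
    flat = cube.flat_spectra()
    corrected = baseline_correct(flat, cube.axis, config.baseline_method,
                                 anchors=config.anchor_wavenumbers)
    amide_idx = cube.axis.index_nearest(config.snr_signal_band)
    amide_raw = corrected[:, amide_idx].copy()
    tissue = amide_raw >= config.background_floor

    out = corrected.copy()
    if config.norm_method == "amide_I_peak":
        out[tissue] = corrected[tissue] / amide_raw[tissue, None]
    elif config.norm_method == "unit_vector":
        norms = np.linalg.norm(corrected[tissue], axis=1)
        ok = norms > 0
        rows = np.nonzero(tissue)[0]
        out[rows[ok]] = corrected[rows[ok]] / norms[ok, None]
        tissue[rows[~ok]] = False

    out = savgol_smooth(out, config.savgol_window, config.savgol_order)

    H, W, B = cube.shape
    processed = HyperspectralCube(
        data=out.reshape(H, W, B), axis=cube.axis, pixel_size=cube.pixel_size,
        valid_mask=tissue.reshape(H, W))
    manifest = config.manifest()
    manifest["amide_raw"] = amide_raw.reshape(H, W)
    manifest["n_background"] = int((~tissue).sum())
    return processed, manifest
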