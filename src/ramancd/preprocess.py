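"""Spectral pre-treatment: cosmic-ray removal, shape-based background
subtraction, Savitzky-Golay noise reduction -- applied in that fixed order.

The order is not configurable: smoothing before spike removal would blur
cosmic rays into band-like features, and baseline estimation is more robust
on despiked data.

Cosmic-ray removal (CRR) is threshold-based: a channel is flagged when it
exceeds the median of its +-(2*width) spectral neighbors (itself excluded)
by more than ``dynamic_factor`` times a robust per-spectrum noise sigma
(1.4826 * MAD of first differences / sqrt(2)).  Only flagged runs at most
``width`` channels wide are treated as cosmic rays -- real Raman bands span
many channels -- and repaired by linear interpolation of unflagged
neighbors.  A spectrum whose noise estimate is zero (noise-free synthetic
input) is left untouched: with no noise there is no spike statistic to
threshold against.

Background subtraction is the 1-D rolling-ball equivalent: grayscale
morphological opening with a flat structuring element of ``shape_size_cm1``
(so the estimate never exceeds the signal apart from the noise allowance),
preceded by a median prefilter whose width scales with ``noise_factor``
(medians do not extend the support of spectral features, so compact bands
stay untouched) and followed by a smoothing of the estimate over the
element length.

Noise reduction is a 4th-order, 11-channel Savitzky-Golay filter with
mirror edge padding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import grey_opening, median_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .exceptions import SpectrumTooShortError, ValidationError
from .types import HyperspectralMap, Spectrum

__all__ = [
    "PretreatParams",
    "remove_cosmic_rays",
    "subtract_background_rolling",
    "smooth_savgol",
    "pretreat",
]

_CRR_CHUNK = 64  # rows of spectra processed at once (bounds the window copy)


@dataclass(frozen=True)
class PretreatParams:
    """Parameter log of the three pre-treatment steps (defaults as used
    throughout: CRR width 2 / dynamic factor 8, rolling-ball shape size
    100 cm^-1 / noise factor 1, Savitzky-Golay order 4 / 11 channels)."""

    crr_width: int = 2
    crr_dynamic_factor: float = 8.0
    ball_shape_cm1: float = 100.0
    ball_noise_factor: float = 1.0
    sg_order: int = 4
    sg_window: int = 11


def _as_rows(obj) -> tuple[np.ndarray, np.ndarray]:
    """(spectra_matrix, wavenumbers) view of a Spectrum or map."""
    if isinstance(obj, Spectrum):
        return obj.intensities[None, :], obj.wavenumbers
    if isinstance(obj, HyperspectralMap):
        return obj.flat_spectra(), obj.wavenumbers
    raise ValidationError(f"expected Spectrum or HyperspectralMap, got {type(obj)}")


def _rewrap(obj, rows: np.ndarray, **metadata):
    if isinstance(obj, Spectrum):
        return obj.with_intensities(rows[0])
    cube = rows.reshape(obj.cube.shape)
    return obj.with_cube(cube, **metadata)


def _neighbor_median(y: np.ndarray, width: int) -> np.ndarray:
    """Median over the +-2*width spectral neighbors of each channel,
    excluding the channel itself."""
    n, c = y.shape
    half = 2 * width
    pad = np.pad(y, ((0, 0), (half, half)), mode="edge")
    offsets = [k for k in range(-half, half + 1) if k != 0]
    stack = np.empty((n, c, len(offsets)))
    for j, k in enumerate(offsets):
        stack[:, :, j] = pad[:, half + k : half + k + c]
    return np.median(stack, axis=2)


def _flag_spikes(y: np.ndarray, width: int, dynamic_factor: float) -> np.ndarray:
    med = _neighbor_median(y, width)
    d = np.diff(y, axis=1)
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
    sigma = 1.4826 * mad / np.sqrt(2.0)
    excess = y - med
    cand = excess > dynamic_factor * sigma[:, None]
    cand[sigma <= 0, :] = False
    flags = np.zeros_like(cand)
    for i in np.flatnonzero(cand.any(axis=1)):
        row = cand[i]
        edges = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s <= width:
                flags[i, s:e] = True
    return flags


def remove_cosmic_rays(obj, width: int = 2, dynamic_factor: float = 8.0):
    """Flag and repair cosmic-ray spikes.

    Returns ``(cleaned, flags)`` where ``cleaned`` has the type of the input
    and ``flags`` is a boolean array over channels (and pixels for a map).
    Only flagged channels are altered.
    """
    if width < 1:
        raise ValidationError("width must be >= 1")
    if dynamic_factor <= 0:
        raise ValidationError("dynamic_factor must be positive")
    rows, _ = _as_rows(obj)
    if rows.shape[1] < 2 * width + 3:
        raise SpectrumTooShortError(
            f"need at least {2 * width + 3} channels for width={width}"
        )
    out = rows.copy()
    flags = np.zeros(rows.shape, dtype=bool)
    for lo in range(0, rows.shape[0], _CRR_CHUNK):
        sl = slice(lo, lo + _CRR_CHUNK)
        f = _flag_spikes(rows[sl], width, dynamic_factor)
        flags[sl] = f
        for i in np.flatnonzero(f.any(axis=1)):
            good = ~f[i]
            idx = np.arange(rows.shape[1])
            out[lo + i, f[i]] = np.interp(idx[f[i]], idx[good], rows[lo + i, good])
    if isinstance(obj, Spectrum):
        return _rewrap(obj, out), flags[0]
    return _rewrap(obj, out), flags.reshape(obj.shape + (-1,))


def subtract_background_rolling(
    obj, shape_size_cm1: float = 100.0, noise_factor: float = 1.0
):
    """Shape-based (rolling-ball) background subtraction.

    The background estimate is a morphological opening with a flat element
    of ``shape_size_cm1``; features narrower than the element pass through
    unchanged while broad autofluorescence and CCD offset are removed.
    """
    rows, w = _as_rows(obj)
    spacing = float(np.median(np.diff(w)))
    if shape_size_cm1 <= spacing:
        raise ValidationError(
            f"shape size {shape_size_cm1} cm^-1 must exceed the channel spacing {spacing:g}"
        )
    if noise_factor < 0:
        raise ValidationError("noise_factor must be non-negative")
    se = max(3, int(round(shape_size_cm1 / spacing)))
    pre = rows
    med_w = int(round(6.0 * noise_factor / spacing))
    if med_w >= 2:
        pre = median_filter(rows, size=(1, med_w | 1), mode="nearest")
    bg = grey_opening(pre, size=(1, se), mode="nearest")
    bg = uniform_filter1d(bg, size=se, axis=1, mode="nearest")
    return _rewrap(obj, rows - bg)


def smooth_savgol(obj, order: int = 4, window_channels: int = 11):
    """Savitzky-Golay least-squares polynomial smoothing (mirror padding)."""
    if window_channels % 2 == 0:
        raise ValidationError("window_channels must be odd")
    if order >= window_channels:
        raise ValidationError("order must be smaller than the window")
    rows, _ = _as_rows(obj)
    if rows.shape[1] < window_channels:
        raise SpectrumTooShortError("spectrum shorter than the smoothing window")
    out = savgol_filter(rows, window_channels, order, axis=1, mode="mirror")
    return _rewrap(obj, out)


def pretreat(obj, params: PretreatParams | None = None):
    """Full pre-treatment: CRR, rolling-ball background, Savitzky-Golay.

    Accepts a map or a single spectrum (e.g. a glucose standard).  For maps
    the applied parameters and the number of repaired spike channels are
    recorded in the metadata under ``'pretreat'``.
    """
    params = params or PretreatParams()
    cleaned, flags = remove_cosmic_rays(
        obj, width=params.crr_width, dynamic_factor=params.crr_dynamic_factor
    )
    cleaned = subtract_background_rolling(
        cleaned, shape_size_cm1=params.ball_shape_cm1, noise_factor=params.ball_noise_factor
    )
    cleaned = smooth_savgol(
        cleaned, order=params.sg_order, window_channels=params.sg_window
    )
    if isinstance(cleaned, Spectrum):
        return cleaned
    log = asdict(params)
    log["spike_channels_repaired"] = int(flags.sum())
    return cleaned.with_cube(cleaned.cube, pretreat=log)
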