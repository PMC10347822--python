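"""Domain types shared by every pipeline stage.

Coordinate convention for all pixel grids: 0-based, row-major, row 0 at the
top, y increasing downward (image convention).  The physical position of the
center of pixel ``(r, c)`` is ``((c + 0.5) * pixel_size, (r + 0.5) *
pixel_size)`` in micrometres.

Intensities are kept as 64-bit floats throughout: raw CCD counts are
integers, but pre-treatment (baseline subtraction, smoothing) produces real
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .exceptions import (
    NonMonotonicAxisError,
    ShapeMismatchError,
    ValidationError,
)

__all__ = [
    "Spectrum",
    "HyperspectralMap",
    "BandWindows",
    "CDMap",
    "L_RANGE",
    "A_RANGE_ROOT",
    "A_RANGE_GLUCOSE",
    "validate_mask",
]


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """One Raman spectrum: a wavenumber axis (cm^-1) and detector counts.

    Invariants: both vectors share one length >= 2, the axis is strictly
    increasing, and all intensities are finite.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = _as_float_vector(self.wavenumbers, "wavenumbers")
        i = _as_float_vector(self.intensities, "intensities")
        if w.size != i.size:
            raise ValidationError(
                f"axis and intensities differ in length: {w.size} vs {i.size}"
            )
        if w.size < 2:
            raise ValidationError("a spectrum needs at least 2 channels")
        if not np.all(np.diff(w) > 0):
            raise NonMonotonicAxisError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValidationError("intensities contain NaN or Inf")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def channel_spacing(self) -> float:
        """Median spacing of the axis in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, intensities)


@dataclass
class HyperspectralMap:
    """Rectangular grid of spectra sharing one wavenumber axis.

    ``cube`` has shape ``(n_rows, n_cols, n_channels)``; ``pixel_size_um`` is
    the physical edge length of one (square) pixel.  ``metadata`` carries
    processing history (e.g. the pre-treatment parameter log).
    """

    wavenumbers: np.ndarray
    cube: np.ndarray
    pixel_size_um: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = _as_float_vector(self.wavenumbers, "wavenumbers")
        cube = np.asarray(self.cube, dtype=np.float64)
        if cube.ndim != 3:
            raise ValidationError(f"cube must be 3-D (rows, cols, channels), got {cube.shape}")
        if cube.shape[2] != w.size:
            raise ShapeMismatchError(
                f"cube has {cube.shape[2]} channels but axis has {w.size}"
            )
        if cube.shape[0] < 1 or cube.shape[1] < 1:
            raise ValidationError("map needs at least one pixel")
        if not np.all(np.diff(w) > 0):
            raise NonMonotonicAxisError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(cube)):
            raise ValidationError("cube contains NaN or Inf")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        self.wavenumbers = w
        self.cube = cube

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.cube.shape[2]

    @property
    def channel_spacing(self) -> float:
        return float(np.median(np.diff(self.wavenumbers)))

    def spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.cube[row, col])

    def flat_spectra(self) -> np.ndarray:
        """All spectra as a ``(n_rows * n_cols, n_channels)`` view."""
        return self.cube.reshape(-1, self.n_channels)

    def with_cube(self, cube: np.ndarray, **metadata_updates) -> "HyperspectralMap":
        md = dict(self.metadata)
        md.update(metadata_updates)
        return HyperspectralMap(self.wavenumbers, cube, self.pixel_size_um, md)


def _check_window(win, name: str) -> tuple[float, float]:
    lo, hi = float(win[0]), float(win[1])
    if not lo < hi:
        raise ValidationError(f"window {name} must have E_min < E_max, got {win}")
    return lo, hi


@dataclass(frozen=True)
class BandWindows:
    """Named integration windows in cm^-1.

    The C-D and C-H stretch windows bracket the Raman-silent region
    (2450-2650 cm^-1), which biological samples leave empty and which is used
    as the internal residual-baseline reference.  ``lignin`` is the narrow
    aryl-ring window used for the lignin distribution map.
    """

    cd: tuple[float, float] = (2040.0, 2300.0)
    ch: tuple[float, float] = (2800.0, 3100.0)
    silent: tuple[float, float] = (2450.0, 2650.0)
    lignin: tuple[float, float] = (1599.0, 1606.0)

    def __post_init__(self):
        cd = _check_window(self.cd, "cd")
        ch = _check_window(self.ch, "ch")
        silent = _check_window(self.silent, "silent")
        _check_window(self.lignin, "lignin")
        if not (cd[1] <= silent[0] and silent[1] <= ch[0]):
            raise ValidationError(
                "windows must be ordered and non-overlapping: cd < silent < ch"
            )
        object.__setattr__(self, "cd", cd)
        object.__setattr__(self, "ch", ch)
        object.__setattr__(self, "silent", silent)
        object.__setattr__(self, "lignin", (float(self.lignin[0]), float(self.lignin[1])))


#: Literature-standard integration windows.
L_RANGE = BandWindows()

#: Data-derived windows for root samples.
A_RANGE_ROOT = BandWindows(cd=(2093.0, 2309.0), ch=(2779.0, 3075.0))

#: Data-derived windows for deuterated-glucose standards.
A_RANGE_GLUCOSE = BandWindows(cd=(2033.0, 2303.0), ch=(2665.0, 3045.0))


def validate_mask(mask, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate a root/void label mask: values in {0, 1}, optional shape check.

    Returns the mask as ``uint8``.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("mask values must be 0 (void) or 1 (root)")
    if shape is not None and m.shape != tuple(shape):
        raise ShapeMismatchError(f"mask shape {m.shape} does not match map shape {shape}")
    return m.astype(np.uint8)


@dataclass
class CDMap:
    """Per-pixel deuterium content with uncertainty.

    ``cd_percent`` holds CD% where it is defined and NaN elsewhere.  A pixel
    is defined when it lies on the root mask, its corrected C-H area is
    non-negative and the corrected C-H + C-D total is positive; this keeps
    every defined value <= 100 while still reporting negative CD% for pixels
    whose corrected C-D area went negative (strong residual background).
    Pixels with |CD%| < 1 are flagged ``low_confidence`` -- band-ratio
    quantification is unreliable below about one percent -- but are not
    suppressed.
    """

    cd_percent: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray
    windows: BandWindows
    negative_area: np.ndarray = None
    low_confidence: np.ndarray = None

    def __post_init__(self):
        cd = np.asarray(self.cd_percent, dtype=np.float64)
        sig = np.asarray(self.sigma, dtype=np.float64)
        self.mask = validate_mask(self.mask, cd.shape)
        if sig.shape != cd.shape:
            raise ShapeMismatchError("sigma and cd_percent must share a shape")
        defined = np.isfinite(cd)
        if np.any(defined & (self.mask == 0)):
            raise ValidationError("cd_percent defined outside the root mask")
        if np.any(cd[defined] > 100.0 + 1e-9):
            raise ValidationError("CD% above 100 must be marked undefined")
        if np.any(sig[np.isfinite(sig)] < 0):
            raise ValidationError("sigma must be non-negative")
        if self.negative_area is None:
            self.negative_area = np.zeros(cd.shape, dtype=bool)
        if self.low_confidence is None:
            self.low_confidence = defined & (np.abs(cd) < 1.0)
        self.cd_percent = cd
        self.sigma = sig

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.cd_percent)

    def mean_cd_percent(self) -> float:
        """Mean CD% over defined root pixels."""
        return float(np.nanmean(self.cd_percent))
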