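"""Lignin mapping and the scalar lignification statistic.

Lignification is the slope of an ordinary least-squares regression of the
per-pixel lignin band area (1599-1606 cm^-1, y) on the per-pixel C-H band
area (x) over root pixels: tissue whose lignin scales steeply with its
structural C-H signal is more mature.  Because both areas scale with laser
power and acquisition time, the slope is invariant to a global intensity
rescaling of the cube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateImageError, ValidationError
from .quantify import snapped_width
from .segment import band_sum_image, residual_background_subtract_images
from .types import BandWindows, HyperspectralMap, L_RANGE, validate_mask

__all__ = ["LignificationResult", "lignin_image", "compute_lignification", "classify_maturity"]


def _corrected_areas(hsmap, mask, windows):
    """Silent-corrected lignin, C-H and C-D band-area images."""
    w = hsmap.wavenumbers
    lig = band_sum_image(hsmap, windows.lignin)
    cd = band_sum_image(hsmap, windows.cd)
    ch = band_sum_image(hsmap, windows.ch)
    sil = band_sum_image(hsmap, windows.silent)
    level = sil / snapped_width(w, windows.silent)
    lig = lig - level * snapped_width(w, windows.lignin)
    cd, ch = residual_background_subtract_images(cd, ch, sil, windows, w)
    return lig, ch, cd


def lignin_image(
    hsmap: HyperspectralMap,
    mask,
    windows: BandWindows = L_RANGE,
    normalize: bool = False,
) -> np.ndarray:
    """Lignin distribution map: silent-corrected lignin band area per pixel,
    gated by the root mask (NaN on void pixels).

    With ``normalize=True`` the image is divided per pixel by the sum of the
    C-H and C-D areas, giving the display-friendly lignin fraction.
    """
    mask = validate_mask(mask, hsmap.shape)
    lig, ch, cd = _corrected_areas(hsmap, mask, windows)
    if normalize:
        total = ch + cd
        with np.errstate(divide="ignore", invalid="ignore"):
            lig = np.where(total > 0, lig / total, np.nan)
    return np.where(mask == 1, lig, np.nan)


@dataclass(frozen=True)
class LignificationResult:
    """OLS fit of lignin area on C-H area across root pixels; the slope is
    the lignification."""

    slope: float
    intercept: float
    r_squared: float
    n_pixels: int
    n_excluded: int

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValidationError("lignification slope must be finite")


def compute_lignification(
    hsmap: HyperspectralMap, mask, windows: BandWindows = L_RANGE
) -> LignificationResult:
    """Regress per-pixel lignin area on C-H area; report the slope.

    Root pixels whose corrected C-H area is non-positive carry no
    structural signal; they are excluded from the regression and counted in
    ``n_excluded``.
    """
    mask = validate_mask(mask, hsmap.shape)
    lig, ch, _ = _corrected_areas(hsmap, mask, windows)
    on_root = mask.astype(bool)
    usable = on_root & (ch > 0)
    x = ch[usable]
    y = lig[usable]
    n_excluded = int(on_root.sum() - usable.sum())
    if x.size < 3:
        raise ValidationError("need at least 3 root pixels with positive C-H area")
    if np.ptp(x) == 0:
        raise DegenerateImageError("all C-H areas equal; slope undefined")
    res = stats.linregress(x, y)
    return LignificationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pixels=int(x.size),
        n_excluded=n_excluded,
    )


def classify_maturity(lignification: float, threshold: float = 0.12) -> str:
    """Binary maturity label; slopes at or above the threshold are
    'mature-like' (boundary assigned upward), below it 'young-like'."""
    if not np.isfinite(lignification):
        raise ValidationError("lignification must be finite")
    return "mature-like" if lignification >= threshold else "young-like"
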