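"""Segmentation of a pre-treated map into root (cell wall) and void.

Two routes, mirroring practice:

* *spatially resolved*: band-sum images of the C-D, C-H and silent windows;
  silent-level residual subtraction; Gaussian smoothing (sigma 0.5); Otsu
  thresholding of the summed, smoothed C-H + C-D structure image;
* *bulk*: a two-component spectral decomposition (seeded k-means on
  L2-normalized spectra plus non-negative least-squares de-mixing) whose
  root component -- the one with the larger C-H band area -- is averaged
  into a single bulk root spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter
from scipy.optimize import nnls

from .exceptions import (
    DegenerateImageError,
    EmptyClassError,
    ShapeMismatchError,
    ValidationError,
)
from .quantify import snap_window, snapped_width
from .types import BandWindows, HyperspectralMap, L_RANGE, Spectrum, validate_mask

__all__ = [
    "band_sum_image",
    "residual_background_subtract_images",
    "gaussian_smooth_image",
    "otsu_threshold_bin",
    "otsu_mask",
    "structure_image",
    "segment_otsu",
    "Decomposition",
    "two_component_decomposition",
    "bulk_root_spectrum",
]


def band_sum_image(hsmap: HyperspectralMap, window) -> np.ndarray:
    """Per-pixel trapezoidal integral of intensity over one window (the
    'sum filter' of mapping software), in counts*cm^-1."""
    i0, i1 = snap_window(hsmap.wavenumbers, window)
    seg = hsmap.cube[..., i0 : i1 + 1]
    return np.trapezoid(seg, hsmap.wavenumbers[i0 : i1 + 1], axis=-1)


def residual_background_subtract_images(
    cd_img: np.ndarray,
    ch_img: np.ndarray,
    silent_img: np.ndarray,
    windows: BandWindows = L_RANGE,
    wavenumbers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the silent-window residual level from the band images.

    Per pixel the silent image is converted to a flat intensity level
    (area / silent width) and removed from each band image in area terms.
    When the map axis is given, window widths are the snapped widths used by
    :func:`band_sum_image`, which makes the cancellation of a flat offset
    exact.
    """
    cd_img = np.asarray(cd_img, dtype=float)
    ch_img = np.asarray(ch_img, dtype=float)
    silent_img = np.asarray(silent_img, dtype=float)
    if not (cd_img.shape == ch_img.shape == silent_img.shape):
        raise ShapeMismatchError("band images must share one shape")
    if wavenumbers is not None:
        w_cd = snapped_width(wavenumbers, windows.cd)
        w_ch = snapped_width(wavenumbers, windows.ch)
        w_sil = snapped_width(wavenumbers, windows.silent)
    else:
        w_cd = windows.cd[1] - windows.cd[0]
        w_ch = windows.ch[1] - windows.ch[0]
        w_sil = windows.silent[1] - windows.silent[0]
    level = silent_img / w_sil
    return cd_img - level * w_cd, ch_img - level * w_ch


def gaussian_smooth_image(image: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries; sigma 0 is the identity."""
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    return gaussian_filter(image, sigma, mode="reflect")


def otsu_threshold_bin(image: np.ndarray, n_bins: int = 256) -> tuple[int, np.ndarray]:
    """Otsu threshold on a min-max scaled histogram.

    Returns ``(t, bin_index)``: the cut bin maximizing the between-class
    variance (ties broken toward the lower threshold) and each pixel's bin.
    Pixels in bins strictly above ``t`` belong to the upper (root) class.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if not hi > lo:
        raise DegenerateImageError("constant image cannot be thresholded")
    scaled = (img - lo) / (hi - lo)
    bins = np.minimum((scaled * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(bins.ravel(), minlength=n_bins)
    # exact integer arithmetic: the between-class variance of cut t is
    # (S0*W1 - S1*W0)^2 / (W0*W1) up to the constant 1/N^2; comparing
    # cross-multiplied Python ints is tie-stable and bit-reproducible.
    counts = [int(c) for c in hist]
    weighted = [k * c for k, c in enumerate(counts)]
    n_total = sum(counts)
    s_total = sum(weighted)
    best_t, best_num, best_den = 0, -1, 1
    w0 = s0 = 0
    for t in range(n_bins - 1):
        w0 += counts[t]
        s0 += weighted[t]
        w1 = n_total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (s_total - s0) * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: ties keep the lower t
            best_t, best_num, best_den = t, num, den
    return best_t, bins


def otsu_mask(structure_image: np.ndarray) -> np.ndarray:
    """Root/void mask: 1 where the structure image exceeds the Otsu threshold."""
    t, bins = otsu_threshold_bin(structure_image)
    return (bins > t).astype(np.uint8)


def structure_image(
    hsmap: HyperspectralMap, windows: BandWindows = L_RANGE, sigma: float = 0.5
) -> np.ndarray:
    """Structure image for masking: smoothed C-H + smoothed C-D after
    silent-residual subtraction."""
    cd_img = band_sum_image(hsmap, windows.cd)
    ch_img = band_sum_image(hsmap, windows.ch)
    sil_img = band_sum_image(hsmap, windows.silent)
    cd_img, ch_img = residual_background_subtract_images(
        cd_img, ch_img, sil_img, windows, hsmap.wavenumbers
    )
    return gaussian_smooth_image(ch_img, sigma) + gaussian_smooth_image(cd_img, sigma)


def segment_otsu(
    hsmap: HyperspectralMap, windows: BandWindows = L_RANGE, sigma: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Otsu segmentation route; returns ``(mask, structure_image)``."""
    img = structure_image(hsmap, windows, sigma)
    return otsu_mask(img), img


@dataclass
class Decomposition:
    """Two-component spectral decomposition of a map.

    ``component_spectra`` has shape (k, n_channels); ``abundances`` holds the
    per-pixel non-negative least-squares loadings; ``labels`` the hard
    cluster assignment; ``root_index`` the component with the larger C-H
    band area.
    """

    component_spectra: np.ndarray
    abundances: np.ndarray
    labels: np.ndarray
    root_index: int
    wavenumbers: np.ndarray

    @property
    def root_mask(self) -> np.ndarray:
        return (self.labels == self.root_index).astype(np.uint8)

    def root_spectrum(self) -> Spectrum:
        return Spectrum(self.wavenumbers, self.component_spectra[self.root_index])


def two_component_decomposition(
    hsmap: HyperspectralMap,
    k: int = 2,
    seed: int = 0,
    windows: BandWindows = L_RANGE,
) -> Decomposition:
    """Endmember-style decomposition: seeded k-means on L2-normalized spectra,
    component spectra as class means, NNLS de-mixing of every pixel.

    The component with the larger C-H band area is labeled root; void
    abundance images complement it.  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    x = hsmap.flat_spectra()
    norms = np.linalg.norm(x, axis=1)
    xn = np.where(norms[:, None] > 0, x / np.where(norms == 0, 1.0, norms)[:, None], 0.0)
    if np.unique(np.round(xn, 10), axis=0).shape[0] < k:
        raise ValidationError(f"map has fewer than k={k} distinct spectra")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(xn)
    labels_flat = km.labels_
    comps = np.stack([x[labels_flat == j].mean(axis=0) for j in range(k)])

    i0, i1 = snap_window(hsmap.wavenumbers, windows.ch)
    ch_areas = np.trapezoid(
        comps[:, i0 : i1 + 1], hsmap.wavenumbers[i0 : i1 + 1], axis=1
    )
    root_index = int(np.argmax(ch_areas))

    a = comps.T  # (channels, k)
    abund = np.empty((x.shape[0], k))
    for i in range(x.shape[0]):
        abund[i], _ = nnls(a, x[i])
    shape = hsmap.shape
    return Decomposition(
        component_spectra=comps,
        abundances=abund.reshape(shape + (k,)),
        labels=labels_flat.reshape(shape),
        root_index=root_index,
        wavenumbers=hsmap.wavenumbers,
    )


def bulk_root_spectrum(hsmap: HyperspectralMap, mask_or_decomposition) -> Spectrum:
    """Unweighted mean spectrum over root pixels; void spectra are discarded."""
    if isinstance(mask_or_decomposition, Decomposition):
        mask = mask_or_decomposition.root_mask
    else:
        mask = validate_mask(mask_or_decomposition, hsmap.shape)
    if not mask.any():
        raise EmptyClassError("no root pixels to average")
    spectra = hsmap.cube[mask.astype(bool)]
    return Spectrum(hsmap.wavenumbers, spectra.mean(axis=0))
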