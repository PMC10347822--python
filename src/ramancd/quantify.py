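"""Band-area quantification of deuterium content.

The central quantity is the fraction of carbon-bound hydrogen replaced by
deuterium, estimated from integrated band areas::

    CD% = A_CD / (A_CH + A_CD) * 100

All areas are differences of one cumulative (primitive) integral of the
spectrum, evaluated at integration limits snapped to the nearest channel of
the native axis.  Residual baseline is removed with the spectrum's own
Raman-silent region (2450-2650 cm^-1): whatever average level survives
pre-treatment there is treated as a flat offset under the nearby C-D and C-H
bands and subtracted in area terms.

Uncertainty follows Gaussian error propagation over two perturbations: a
widening of each integration limit by ``delta_E`` and a flat baseline shift
of ``delta_I`` counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats
from scipy.ndimage import uniform_filter1d

from .exceptions import (
    CalibrationError,
    NoBandError,
    ShapeMismatchError,
    ValidationError,
    WindowOutsideAxisError,
)
from .types import BandWindows, CDMap, HyperspectralMap, L_RANGE, Spectrum, validate_mask

__all__ = [
    "snap_window",
    "PrimitiveIntegral",
    "primitive_integral",
    "band_area",
    "silent_region_correction",
    "compute_cd_percent",
    "cd_map",
    "determine_a_range",
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "UncertaintyBudget",
    "propagate_uncertainty",
    "bulk_cd_percent",
    "rayleigh_resolution",
    "scan_grid",
]


# ----------------------------------------------------------------- windows

def snap_window(wavenumbers: np.ndarray, window) -> tuple[int, int]:
    """Snap window bounds to the nearest channels; return (i_min, i_max).

    Snapping makes band areas reproducible across axes whose channels do not
    fall exactly on the nominal limits.
    """
    w = np.asarray(wavenumbers, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValidationError(f"window must have E_min < E_max, got {window}")
    if lo < w[0] or hi > w[-1]:
        raise WindowOutsideAxisError(
            f"window {window} outside axis [{w[0]:g}, {w[-1]:g}]"
        )
    i0 = int(np.argmin(np.abs(w - lo)))
    i1 = int(np.argmin(np.abs(w - hi)))
    return i0, i1


def snapped_width(wavenumbers: np.ndarray, window) -> float:
    i0, i1 = snap_window(wavenumbers, window)
    return float(wavenumbers[i1] - wavenumbers[i0])


# ------------------------------------------------------- primitive integral

@dataclass(frozen=True)
class PrimitiveIntegral:
    """Cumulative trapezoidal integral A_I(E) of one spectrum.

    ``values[k]`` is the integral from the first channel to channel ``k``;
    calling the object evaluates A_I at an arbitrary energy by snapping to
    the nearest channel.
    """

    wavenumbers: np.ndarray
    values: np.ndarray

    def __call__(self, energy: float) -> float:
        w = self.wavenumbers
        if energy < w[0] or energy > w[-1]:
            raise WindowOutsideAxisError(f"E={energy:g} outside axis")
        return float(self.values[int(np.argmin(np.abs(w - energy)))])


def primitive_integral(spectrum: Spectrum) -> PrimitiveIntegral:
    """Cumulative trapezoidal integral on the native axis, zero at the start."""
    vals = integrate.cumulative_trapezoid(
        spectrum.intensities, spectrum.wavenumbers, initial=0.0
    )
    return PrimitiveIntegral(spectrum.wavenumbers, vals)


def band_area(a_i: PrimitiveIntegral, window) -> float:
    """Band area as a difference of two primitive-integral evaluations."""
    i0, i1 = snap_window(a_i.wavenumbers, window)
    return float(a_i.values[i1] - a_i.values[i0])


def silent_region_correction(
    a_i: PrimitiveIntegral, windows: BandWindows = L_RANGE
) -> tuple[float, float, float]:
    """Silent-region residual-baseline correction of the C-H and C-D areas.

    The integrated area over the Raman-silent window should vanish; whatever
    level ``b`` remains is interpreted as a flat residual offset and removed
    from each band area as ``b * band_width``.  Returns
    ``(A_CH_corrected, A_CD_corrected, b)``.
    """
    w = a_i.wavenumbers
    b = band_area(a_i, windows.silent) / snapped_width(w, windows.silent)
    a_ch = band_area(a_i, windows.ch) - b * snapped_width(w, windows.ch)
    a_cd = band_area(a_i, windows.cd) - b * snapped_width(w, windows.cd)
    return a_ch, a_cd, b


def compute_cd_percent(a_ch, a_cd):
    """CD% = A_CD / (A_CH + A_CD) * 100; NaN marks undefined pixels.

    Undefined: total area non-positive (nothing to ratio) or corrected C-H
    area negative (no structural signal; a ratio above 100 would be
    meaningless).  Negative CD% from a negative corrected C-D area is kept.
    Accepts scalars or arrays.
    """
    a_ch = np.asarray(a_ch, dtype=float)
    a_cd = np.asarray(a_cd, dtype=float)
    total = a_ch + a_cd
    defined = (total > 0) & (a_ch >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(defined, a_cd / np.where(total == 0, np.nan, total) * 100.0, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


# ----------------------------------------------------------------- CD maps

def _cumtrap_cube(cube: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    return integrate.cumulative_trapezoid(cube, wavenumbers, axis=-1, initial=0.0)


def _band_areas_from_ct(ct: np.ndarray, wavenumbers, window) -> np.ndarray:
    i0, i1 = snap_window(wavenumbers, window)
    return ct[..., i1] - ct[..., i0]


def cd_map(
    hsmap: HyperspectralMap,
    mask,
    windows: BandWindows = L_RANGE,
    delta_E: float = 10.0,
    delta_I: float = 1.0,
    calibration: "CalibrationModel | None" = None,
) -> CDMap:
    """Per-pixel CD% with uncertainty, gated by the root mask.

    Per pixel: band areas over the snapped windows, silent-region residual
    correction, the band-area ratio, and Gaussian propagation of the
    ``delta_E`` / ``delta_I`` perturbations.  Void pixels (mask 0) and pixels
    without usable corrected areas carry NaN.
    """
    mask = validate_mask(mask, hsmap.shape)
    w = hsmap.wavenumbers
    ct = _cumtrap_cube(hsmap.cube, w)

    w_cd = snapped_width(w, windows.cd)
    w_ch = snapped_width(w, windows.ch)
    w_sil = snapped_width(w, windows.silent)

    a_cd_raw = _band_areas_from_ct(ct, w, windows.cd)
    a_ch_raw = _band_areas_from_ct(ct, w, windows.ch)
    b = _band_areas_from_ct(ct, w, windows.silent) / w_sil
    a_cd = a_cd_raw - b * w_cd
    a_ch = a_ch_raw - b * w_ch

    cd = compute_cd_percent(a_ch, a_cd)
    cd = np.where(mask == 1, cd, np.nan)

    # limit-widening component of the uncertainty, vectorized over pixels
    wide_cd = (windows.cd[0] - delta_E, windows.cd[1] + delta_E)
    wide_ch = (windows.ch[0] - delta_E, windows.ch[1] + delta_E)
    d_cd_lim = np.abs(_band_areas_from_ct(ct, w, wide_cd) - a_cd_raw)
    d_ch_lim = np.abs(_band_areas_from_ct(ct, w, wide_ch) - a_ch_raw)
    d_cd = np.hypot(d_cd_lim, delta_I * w_cd)
    d_ch = np.hypot(d_ch_lim, delta_I * w_ch)

    total = a_ch + a_cd
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = (
            100.0
            / total**2
            * np.hypot(a_ch * d_cd, a_cd * d_ch)
        )
    sigma = np.where(np.isfinite(cd), np.abs(sigma), np.nan)

    if calibration is not None:
        cd = np.where(np.isfinite(cd), apply_calibration(calibration, cd), np.nan)
        sigma = sigma / abs(calibration.slope)

    return CDMap(
        cd_percent=cd,
        sigma=sigma,
        mask=mask,
        windows=windows,
        negative_area=(a_cd < 0) & (mask == 1),
    )


# ------------------------------------------------------------ A-range edges

_DEFAULT_SEARCH = {"cd": (1900.0, 2420.0), "ch": (2680.0, 3250.0)}


def determine_a_range(
    spectra,
    which_band: str,
    edge_fraction: float = 0.05,
    search_window=None,
    min_snr: float = 5.0,
) -> tuple[float, float]:
    """Data-derived integration range for one band, averaged over spectra.

    Per spectrum the band edges are the outermost wavenumbers at which the
    lightly smoothed intensity exceeds ``edge_fraction`` of the band maximum
    above the local baseline (the minimum inside the search window); the
    returned range is the mean of the per-spectrum edges.  Spectra whose band
    never rises ``min_snr`` robust-sigmas above the baseline raise
    :class:`NoBandError`.
    """
    if which_band not in ("cd", "ch"):
        raise ValidationError("which_band must be 'cd' or 'ch'")
    if not 0 < edge_fraction < 1:
        raise ValidationError("edge_fraction must lie in (0, 1)")
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    search = search_window or _DEFAULT_SEARCH[which_band]
    lows, highs = [], []
    for spec in spectra:
        w = spec.wavenumbers
        i0, i1 = snap_window(w, search)
        seg_w = w[i0 : i1 + 1]
        smooth_n = max(3, int(round(2.0 / spec.channel_spacing)))
        seg = uniform_filter1d(spec.intensities, smooth_n, mode="nearest")[i0 : i1 + 1]
        base = float(seg.min())
        peak = float(seg.max())
        noise = 1.4826 * float(np.median(np.abs(np.diff(spec.intensities)))) / np.sqrt(2)
        if peak - base <= min_snr * noise or peak <= base:
            raise NoBandError(
                f"no {which_band} band above the noise floor in {search}"
            )
        thr = base + edge_fraction * (peak - base)
        above = np.flatnonzero(seg >= thr)
        lows.append(float(seg_w[above[0]]))
        highs.append(float(seg_w[above[-1]]))
    return float(np.mean(lows)), float(np.mean(highs))


# ------------------------------------------------------------- calibration

@dataclass(frozen=True)
class CalibrationModel:
    """Straight-line response of measured CD% to true (prepared) CD%.

    ``measured = slope * true + intercept``; applying the model inverts the
    line.  The intercept is fitted (not forced through the origin) and
    reported so the choice is auditable.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sigma: float
    standards: tuple = field(default_factory=tuple)

    def apply(self, measured):
        return apply_calibration(self, measured)


def fit_calibration(standards) -> CalibrationModel:
    """Ordinary least squares of measured CD% on true CD%.

    ``standards`` is a sequence of ``(true_percent, measured_percent)``
    pairs; at least two distinct true values are required and the fitted
    slope must be non-zero for invertibility.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need >= 2 (true, measured) standards")
    true, meas = arr[:, 0], arr[:, 1]
    if np.unique(true).size < 2:
        raise CalibrationError("standards share one true value; line is undefined")
    res = stats.linregress(true, meas)
    if res.slope == 0:
        raise CalibrationError("zero slope; calibration is not invertible")
    resid = meas - (res.slope * true + res.intercept)
    dof = max(1, true.size - 2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sigma=float(np.sqrt(np.sum(resid**2) / dof)),
        standards=tuple(map(tuple, arr)),
    )


def apply_calibration(model: CalibrationModel, cd_value):
    """Invert the standards line: calibrated = (measured - intercept) / slope."""
    if model.slope == 0:
        raise CalibrationError("zero slope; calibration is not invertible")
    return (np.asarray(cd_value, dtype=float) - model.intercept) / model.slope if np.ndim(
        cd_value
    ) else (float(cd_value) - model.intercept) / model.slope


# -------------------------------------------------------------- uncertainty

@dataclass(frozen=True)
class UncertaintyBudget:
    """Gaussian error budget of one CD% value.

    Components per band: ``dA_limits`` from widening both integration limits
    by ``delta_E`` and ``dA_baseline = delta_I * band_width`` from a flat
    baseline shift; combined in quadrature and propagated through the ratio.
    """

    delta_E: float
    delta_I: float
    d_a_ch: float
    d_a_cd: float
    d_cd_percent: float
    a_ch: float
    a_cd: float


def propagate_uncertainty(
    spectrum: Spectrum,
    windows: BandWindows = L_RANGE,
    delta_E: float = 10.0,
    delta_I: float = 1.0,
) -> UncertaintyBudget:
    """Error budget of the CD% of one (pre-treated) spectrum."""
    if delta_E < 0 or delta_I < 0:
        raise ValidationError("perturbations must be non-negative")
    a_i = primitive_integral(spectrum)
    w = spectrum.wavenumbers
    a_ch, a_cd, _ = silent_region_correction(a_i, windows)
    total = a_ch + a_cd
    if total == 0:
        raise ValidationError("A_CH + A_CD is zero; CD% undefined")

    def one_band(window):
        raw = band_area(a_i, window)
        wide = (window[0] - delta_E, window[1] + delta_E)
        d_lim = abs(band_area(a_i, wide) - raw)
        d_base = delta_I * snapped_width(w, window)
        return float(np.hypot(d_lim, d_base))

    d_ch = one_band(windows.ch)
    d_cd = one_band(windows.cd)
    # dCD/dA_CD = 100 * A_CH / T^2 ; dCD/dA_CH = -100 * A_CD / T^2
    d_cdp = 100.0 / total**2 * float(np.hypot(a_ch * d_cd, a_cd * d_ch))
    return UncertaintyBudget(
        delta_E=delta_E,
        delta_I=delta_I,
        d_a_ch=d_ch,
        d_a_cd=d_cd,
        d_cd_percent=d_cdp,
        a_ch=a_ch,
        a_cd=a_cd,
    )


def bulk_cd_percent(
    spectrum: Spectrum,
    windows: BandWindows = L_RANGE,
    delta_E: float = 10.0,
    delta_I: float = 1.0,
    calibration: CalibrationModel | None = None,
) -> tuple[float, UncertaintyBudget]:
    """CD% (and its error budget) of one averaged root spectrum."""
    a_i = primitive_integral(spectrum)
    a_ch, a_cd, _ = silent_region_correction(a_i, windows)
    cd = compute_cd_percent(a_ch, a_cd)
    budget = propagate_uncertainty(spectrum, windows, delta_E, delta_I)
    if calibration is not None and np.isfinite(cd):
        cd = apply_calibration(calibration, cd)
        budget = UncertaintyBudget(
            delta_E=budget.delta_E,
            delta_I=budget.delta_I,
            d_a_ch=budget.d_a_ch,
            d_a_cd=budget.d_a_cd,
            d_cd_percent=budget.d_cd_percent / abs(calibration.slope),
            a_ch=budget.a_ch,
            a_cd=budget.a_cd,
        )
    return cd, budget


# ------------------------------------------------- closed-form utilities

def rayleigh_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """Rayleigh lateral resolution 0.61 * lambda / NA, in nanometres."""
    if wavelength_nm <= 0:
        raise ValidationError("wavelength must be positive")
    if not 0 < numerical_aperture <= 1.5:
        raise ValidationError("numerical aperture must lie in (0, 1.5]")
    return 0.61 * wavelength_nm / numerical_aperture


def scan_grid(length_um: float, width_um: float, pixel_um: float) -> tuple[int, int, int]:
    """Scan-raster arithmetic: (n_cols, n_rows, n_spectra) of a strip scan."""
    if length_um <= 0 or width_um <= 0 or pixel_um <= 0:
        raise ValidationError("dimensions must be positive")
    n_cols = int(np.floor(length_um / pixel_um))
    n_rows = int(np.floor(width_um / pixel_um))
    return n_cols, n_rows, n_cols * n_rows
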