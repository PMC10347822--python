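"""Synthetic hyperspectral scenes with known ground truth.

The generator emulates a vibratome-cut root cross-section scanned by
confocal Raman mapping: cell-wall pixels carry a plant-like spectrum whose
C-H stretch intensity is partially transferred to the C-D stretch region
according to a per-pixel deuteration fraction, plus a lignin aryl band and
fingerprint scenery; lumen/void pixels carry only background and noise.

Two constructions make the whole downstream pipeline analytically
invertible in the noise-free limit:

* each composite band profile is truncated to a compact support narrower
  than the rolling-ball structuring element (100 cm^-1), so shape-based
  baseline estimation passes under the bands exactly;
* each profile is normalized so that its trapezoidal area over the snapped
  default integration window equals one, so a root pixel with deuteration
  fraction ``f`` and total band area ``A`` has C-D area exactly ``f * A``
  and C-H area exactly ``(1 - f) * A``.

Consequently the recovered CD% equals ``100 * f`` to machine precision
without noise, and all stochastic elements derive from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .quantify import snap_window
from .types import BandWindows, HyperspectralMap, L_RANGE, Spectrum

__all__ = [
    "BandModel",
    "BandLibrary",
    "TruthParams",
    "NoiseParams",
    "SceneTruth",
    "default_axis",
    "generate_root_cube",
    "generate_glucose_standard",
    "inject_cosmic_rays",
    "unit_profiles",
]


def default_axis(start: float = 950.0, stop: float = 3500.0, step: float = 0.25) -> np.ndarray:
    """Default wavenumber axis (cm^-1).

    Deliberately oversampled (0.25 cm^-1/channel) relative to a CCD
    spectrograph so that channel-domain filters are effectively
    shape-preserving on the synthetic bands.
    """
    return np.arange(start, stop + step / 2, step)


@dataclass(frozen=True)
class BandModel:
    """One Gaussian Raman band: center and width in cm^-1, amplitude in counts.

    ``truncate_at`` clips the profile to ``center +- truncate_at * width``;
    band shapes do not matter to windowed areas, compact support does (see
    module docstring).
    """

    center: float
    width: float
    amplitude: float = 1.0
    assignment: str = ""
    truncate_at: float = 5.3

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError("band width must be positive")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be non-negative")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        z = (axis - self.center) / self.width
        p = self.amplitude * np.exp(-0.5 * z * z)
        p[np.abs(z) > self.truncate_at] = 0.0
        return p


def _composite(axis, bands) -> np.ndarray:
    out = np.zeros_like(axis)
    for b in bands:
        out += b.profile(axis)
    return out


@dataclass(frozen=True)
class BandLibrary:
    """Band models for the root (or glucose) spectrum.

    The C-H stretch is a composite of the cellulose (2895 cm^-1) and lignin
    (2935 cm^-1) contributions; the C-D stretch sits near 2170 cm^-1, well
    inside the literature window; the lignin aryl-ring band at ~1602 cm^-1
    feeds the lignin distribution map.  Fingerprint bands are scenery and
    stay below 1700 cm^-1.
    """

    ch: tuple = (
        BandModel(2895.0, 5.5, 1.0, "cellulose C-H stretch"),
        BandModel(2935.0, 5.5, 0.6, "lignin C-H stretch"),
    )
    cd: tuple = (BandModel(2170.0, 9.0, 1.0, "C-D stretch"),)
    lignin: BandModel = BandModel(1602.0, 8.0, 1.0, "lignin aryl-ring stretch")
    fingerprint: tuple = (
        BandModel(983.0, 7.0, 0.10, "cellulose C-C/C-O stretch"),
        BandModel(1095.0, 7.0, 0.15, "cellulose C-C/C-O stretch"),
        BandModel(1122.0, 7.0, 0.12, "cellulose C-O-C stretch"),
        BandModel(1377.0, 7.0, 0.10, "cellulose HCC/HCO bending"),
        BandModel(1457.0, 7.0, 0.08, "lignin/cellulose CH2 deformation"),
        BandModel(1690.0, 8.0, 0.05, "coniferyl C=O stretch"),
    )


def unit_profiles(
    axis: np.ndarray, library: BandLibrary | None = None, windows: BandWindows = L_RANGE
) -> dict[str, np.ndarray]:
    """Band profiles normalized to unit trapezoidal area over their snapped window.

    Keys ``ch``, ``cd``, ``lignin`` (window-normalized) and ``fingerprint``
    (normalized to unit total area).  These are the exact building blocks
    the generator uses, exposed so tests can derive closed-form truths.
    """
    library = library or BandLibrary()

    def _norm(profile, window):
        i0, i1 = snap_window(axis, window)
        area = np.trapezoid(profile[i0 : i1 + 1], axis[i0 : i1 + 1])
        if area <= 0:
            # window degenerates on a coarse axis: fall back to total area
            area = np.trapezoid(profile, axis)
        if area <= 0:
            raise ValidationError("band profile has no area on this axis")
        return profile / area

    ch = _norm(_composite(axis, library.ch), windows.ch)
    cd = _norm(_composite(axis, library.cd), windows.cd)
    lig = _norm(library.lignin.profile(axis), windows.lignin)
    fing = _composite(axis, library.fingerprint)
    total = np.trapezoid(fing, axis)
    if total > 0:
        fing = fing / total
    return {"ch": ch, "cd": cd, "lignin": lig, "fingerprint": fing}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth scene description.

    ``cd_fraction`` is the fraction of C-H stretch intensity transferred to
    the C-D band (scalar or per-pixel grid); ``lignin_ch_ratio`` couples the
    lignin band area to the per-pixel C-H area, so it is also the expected
    lignification slope.  ``total_band_area`` is the per-pixel C-H + C-D
    area in counts*cm^-1 before the +-``area_variation`` uniform jitter that
    gives pixels distinct intensities.
    """

    cd_fraction: float | np.ndarray = 0.2
    lignin_ch_ratio: float = 0.1
    lignin_gradient: tuple[float, float] | None = None
    geometry: str = "voronoi"
    n_cells: int | None = None
    total_band_area: float = 5000.0
    area_variation: float = 0.3
    fingerprint_scale: float = 0.02


@dataclass(frozen=True)
class NoiseParams:
    """Instrumental nuisance model.

    Autofluorescence background: per-pixel scaled broad Gaussian tail
    (center below the axis start, sigma >= 300 cm^-1) that decays through
    the fingerprint region and is essentially flat beyond ~2000 cm^-1, plus
    a gentle linear term and a CCD offset of a few counts.  Cosmic-ray
    spikes are 1-2 channel positive excursions at a Poisson rate per
    spectrum.
    """

    background_amplitude: float = 150.0
    background_center: float = 650.0
    background_sigma: float = 350.0
    background_jitter: float = 0.5
    linear_slope_counts: float = 5.0
    offset_counts: float = 1.5
    offset_jitter: float = 3.0
    noise_sigma: float = 3.0
    spike_rate: float = 0.3
    spike_amplitude: tuple[float, float] = (100.0, 1000.0)

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free limit: no background, no offset, no noise, no spikes."""
        return cls(
            background_amplitude=0.0,
            background_jitter=0.0,
            linear_slope_counts=0.0,
            offset_counts=0.0,
            offset_jitter=0.0,
            noise_sigma=0.0,
            spike_rate=0.0,
        )


@dataclass
class SceneTruth:
    """Everything the generator knows: mask, per-pixel deuteration fraction,
    lignin band weight (window-area units), per-pixel total band area, spike
    channels per pixel, and the seed."""

    mask: np.ndarray
    cd_fraction: np.ndarray
    lignin_weight: np.ndarray
    total_area: np.ndarray
    spike_channels: dict
    seed: int


def _voronoi_walls(n_rows: int, n_cols: int, n_cells: int, rng) -> np.ndarray:
    """Cell-wall mask: ridges between Voronoi cells inside an elliptical
    root footprint, mimicking walls around empty lumina."""
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
    inside = ((rr - cy) / (0.48 * n_rows)) ** 2 + ((cc - cx) / (0.48 * n_cols)) ** 2 <= 1.0
    pts = np.column_stack(
        [rng.uniform(0, n_rows, n_cells), rng.uniform(0, n_cols, n_cells)]
    )
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    label = np.argmin(d2, axis=-1)
    wall = np.zeros((n_rows, n_cols), dtype=bool)
    wall[:, :-1] |= label[:, :-1] != label[:, 1:]
    wall[:, 1:] |= label[:, :-1] != label[:, 1:]
    wall[:-1, :] |= label[:-1, :] != label[1:, :]
    wall[1:, :] |= label[:-1, :] != label[1:, :]
    rim = inside & ~np.roll(inside, 1, 0) | inside & ~np.roll(inside, -1, 0)
    rim |= inside & ~np.roll(inside, 1, 1) | inside & ~np.roll(inside, -1, 1)
    mask = (wall | rim) & inside
    if not mask.any():  # tiny grids: fall back to the footprint itself
        mask = inside
    return mask.astype(np.uint8)


def _ring_walls(n_rows: int, n_cols: int) -> np.ndarray:
    """Concentric-ring walls (stele-like), deterministic."""
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
    r = np.hypot((rr - cy) / (0.48 * n_rows), (cc - cx) / (0.48 * n_cols))
    mask = np.zeros((n_rows, n_cols), dtype=np.uint8)
    for radius in (0.33, 0.66, 1.0):
        mask[np.abs(r - radius) < 0.09] = 1
    return mask


def _background(axis, params: NoiseParams, scale: float, slope: float, offset: float):
    span = axis[-1] - axis[0]
    bg = params.background_amplitude * scale * np.exp(
        -0.5 * ((axis - params.background_center) / params.background_sigma) ** 2
    )
    return bg + slope * (axis - axis[0]) / span + offset


def generate_root_cube(
    n_rows: int = 20,
    n_cols: int = 30,
    pixel_size_um: float = 2.0,
    band_library: BandLibrary | None = None,
    truth_params: TruthParams | None = None,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    axis: np.ndarray | None = None,
    windows: BandWindows = L_RANGE,
) -> tuple[HyperspectralMap, SceneTruth]:
    """Generate a root-like hyperspectral cube and its ground truth.

    Root pixels: ``A * [(1-f) p_CH + f p_CD] + w_lig p_lig + fingerprints +
    background + offset + noise + spikes`` with window-normalized profiles;
    void pixels carry background and noise only.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("grid dimensions must be positive")
    truth_params = truth_params or TruthParams()
    noise_params = noise_params or NoiseParams()
    band_library = band_library or BandLibrary()
    axis = default_axis() if axis is None else np.asarray(axis, dtype=float)
    rng = np.random.default_rng(seed)

    if truth_params.geometry == "voronoi":
        n_cells = truth_params.n_cells or max(3, (n_rows * n_cols) // 40)
        mask = _voronoi_walls(n_rows, n_cols, n_cells, rng)
    elif truth_params.geometry == "rings":
        mask = _ring_walls(n_rows, n_cols)
    elif truth_params.geometry == "full":
        mask = np.ones((n_rows, n_cols), dtype=np.uint8)
    else:
        raise ValidationError(f"unknown geometry {truth_params.geometry!r}")

    f = np.asarray(truth_params.cd_fraction, dtype=float)
    if f.ndim == 0:
        f = np.full((n_rows, n_cols), float(f))
    if f.shape != (n_rows, n_cols):
        raise ValidationError("cd_fraction grid must match the map shape")
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("cd_fraction must lie in [0, 1]")
    f = np.where(mask == 1, f, 0.0)

    profiles = unit_profiles(axis, band_library, windows)
    area = truth_params.total_band_area * (
        1.0 + truth_params.area_variation * rng.uniform(-1, 1, (n_rows, n_cols))
    )
    area = np.where(mask == 1, area, 0.0)

    lig_ratio = np.full((n_rows, n_cols), truth_params.lignin_ch_ratio)
    if truth_params.lignin_gradient is not None:
        lo, hi = truth_params.lignin_gradient
        lig_ratio = lig_ratio * np.linspace(lo, hi, n_cols)[None, :]
    lignin_weight = np.where(mask == 1, lig_ratio * (1.0 - f) * area, 0.0)

    cube = np.zeros((n_rows, n_cols, axis.size))
    signal = (
        area[..., None] * (1.0 - f[..., None]) * profiles["ch"]
        + area[..., None] * f[..., None] * profiles["cd"]
        + lignin_weight[..., None] * profiles["lignin"]
        + (truth_params.fingerprint_scale * area)[..., None] * profiles["fingerprint"]
    )
    cube += signal

    scale = 1.0 + noise_params.background_jitter * rng.uniform(-1, 1, (n_rows, n_cols))
    slope = rng.uniform(0, noise_params.linear_slope_counts, (n_rows, n_cols))
    offset = noise_params.offset_counts + rng.uniform(
        0, noise_params.offset_jitter, (n_rows, n_cols)
    )
    if (
        noise_params.background_amplitude > 0
        or noise_params.linear_slope_counts > 0
        or noise_params.offset_counts > 0
        or noise_params.offset_jitter > 0
    ):
        tail = noise_params.background_amplitude * np.exp(
            -0.5 * ((axis - noise_params.background_center) / noise_params.background_sigma) ** 2
        )
        ramp = (axis - axis[0]) / (axis[-1] - axis[0])
        cube += (
            scale[..., None] * tail
            + slope[..., None] * ramp
            + offset[..., None]
        )
    if noise_params.noise_sigma > 0:
        cube += rng.normal(0.0, noise_params.noise_sigma, cube.shape)

    spike_channels: dict = {}
    if noise_params.spike_rate > 0:
        lo, hi = noise_params.spike_amplitude
        n_spikes = rng.poisson(noise_params.spike_rate, (n_rows, n_cols))
        for r in range(n_rows):
            for c in range(n_cols):
                chans = []
                for _ in range(int(n_spikes[r, c])):
                    ch0 = int(rng.integers(2, axis.size - 3))
                    width = int(rng.integers(1, 3))
                    amp = rng.uniform(lo, hi)
                    for k in range(width):
                        cube[r, c, ch0 + k] += amp
                        chans.append(ch0 + k)
                if chans:
                    spike_channels[(r, c)] = sorted(chans)

    hsmap = HyperspectralMap(
        axis, cube, pixel_size_um, metadata={"synthetic_seed": int(seed)}
    )
    truth = SceneTruth(
        mask=mask,
        cd_fraction=f,
        lignin_weight=lignin_weight,
        total_area=area,
        spike_channels=spike_channels,
        seed=int(seed),
    )
    return hsmap, truth


def generate_glucose_standard(
    cd_fraction: float,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    axis: np.ndarray | None = None,
    total_band_area: float = 40000.0,
    band_library: BandLibrary | None = None,
    windows: BandWindows = L_RANGE,
) -> Spectrum:
    """Single spectrum of a deuterated-glucose standard of known fraction.

    A dried glucose droplet gives a much stronger, lignin-free spectrum than
    root tissue; the default total band area reflects that.
    """
    if not 0.0 <= cd_fraction <= 1.0:
        raise ValidationError("cd_fraction must lie in [0, 1]")
    noise_params = noise_params or NoiseParams()
    band_library = band_library or BandLibrary()
    axis = default_axis() if axis is None else np.asarray(axis, dtype=float)
    rng = np.random.default_rng(seed)
    profiles = unit_profiles(axis, band_library, windows)
    intens = total_band_area * (
        (1.0 - cd_fraction) * profiles["ch"] + cd_fraction * profiles["cd"]
    )
    intens = intens + 0.02 * total_band_area * profiles["fingerprint"]
    scale = 1.0 + noise_params.background_jitter * rng.uniform(-1, 1)
    slope = rng.uniform(0, noise_params.linear_slope_counts)
    offset = noise_params.offset_counts + rng.uniform(0, noise_params.offset_jitter)
    if noise_params.background_amplitude > 0 or slope > 0 or offset > 0:
        intens = intens + _background(axis, noise_params, scale, slope, offset)
    if noise_params.noise_sigma > 0:
        intens = intens + rng.normal(0.0, noise_params.noise_sigma, axis.size)
    spec = Spectrum(axis, intens)
    if noise_params.spike_rate > 0:
        n = int(rng.poisson(noise_params.spike_rate))
        if n:
            spec, _ = inject_cosmic_rays(
                spec, n, noise_params.spike_amplitude, seed=int(rng.integers(2**31))
            )
    return spec


def inject_cosmic_rays(
    spectrum: Spectrum,
    n_spikes: int,
    amplitude_range: tuple[float, float] = (100.0, 1000.0),
    seed: int = 0,
    width_choices: tuple[int, ...] = (1, 2),
) -> tuple[Spectrum, list[int]]:
    """Add 1-2 channel positive spikes at seeded random channels.

    Returns the spiked spectrum and the sorted list of affected channels (the
    oracle for cosmic-ray-removal tests).
    """
    if n_spikes < 0:
        raise ValidationError("n_spikes must be non-negative")
    lo, hi = amplitude_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValidationError("amplitude_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    intens = spectrum.intensities.copy()
    channels: list[int] = []
    max_w = max(width_choices)
    for _ in range(int(n_spikes)):
        ch0 = int(rng.integers(1, len(spectrum) - max_w - 1))
        width = int(rng.choice(width_choices))
        amp = rng.uniform(lo, hi)
        for k in range(width):
            intens[ch0 + k] += amp
            channels.append(ch0 + k)
    return spectrum.with_intensities(intens), sorted(set(channels))
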