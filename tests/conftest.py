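"""Shared fixtures: small synthetic scenes generated at test time.

Session-scoped cubes amortize the cost of pre-treatment across tests; every
stochastic fixture is built from an explicit seed.
"""

import numpy as np
import pytest

from ramancd import (
    HyperspectralMap,
    NoiseParams,
    Spectrum,
    TruthParams,
    generate_root_cube,
    pretreat,
)


@pytest.fixture(scope="session")
def coarse_axis():
    """Fast 2 cm^-1 axis for mechanics-level tests."""
    return np.arange(1000.0, 3400.0, 2.0)


@pytest.fixture(scope="session")
def cube_noise_free():
    """Noise-free scene, cd_fraction 0.2: the analytically invertible case."""
    hsmap, truth = generate_root_cube(
        10, 12, noise_params=NoiseParams.none(), seed=11
    )
    return hsmap, truth


@pytest.fixture(scope="session")
def cube_noise_free_pre(cube_noise_free):
    hsmap, truth = cube_noise_free
    return pretreat(hsmap), truth


@pytest.fixture(scope="session")
def cube_noisy():
    """Default-noise scene, cd_fraction 0.2."""
    hsmap, truth = generate_root_cube(10, 12, seed=7)
    return hsmap, truth


@pytest.fixture(scope="session")
def cube_noisy_pre(cube_noisy):
    hsmap, truth = cube_noisy
    return pretreat(hsmap), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_flat_spectrum(axis, level=0.0):
    return Spectrum(axis, np.full(axis.size, float(level)))


def gaussian_spectrum(axis, center, sigma, amplitude=1.0, baseline=0.0):
    y = amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2) + baseline
    return Spectrum(axis, y)
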