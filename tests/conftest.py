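import math

import numpy as np
import pytest

import tissuedrt as td
from tissuedrt.core import DRTResult, RelaxationGrid

SQRT_2PI = math.sqrt(2.0 * math.pi)


@pytest.fixture(scope="session")
def grid() -> RelaxationGrid:
    return RelaxationGrid.default()


@pytest.fixture(scope="session")
def frequencies() -> np.ndarray:
    """The standard acquisition grid: 300 log-spaced points, 20 Hz - 400 kHz."""
    return td.default_frequencies()


@pytest.fixture(scope="session")
def debye_spectrum(frequencies):
    """Noiseless single-relaxation spectrum: Z = 100 + 500/(1 + j w 1e-4)."""
    el = td.DispersionElement("debye", 500.0, {"tau0": 1e-4})
    z = 100.0 + td.element_impedance(el, frequencies)
    return td.ImpedanceSpectrum(frequencies, z, {"R_inf": 100.0, "tau0": 1e-4})


def gaussian_curve_drt(components, grid, seed=None, noise_frac=0.0,
                       R_inf=0.0) -> DRTResult:
    """Build a DRT whose curve is an exact sum of Gaussians in natural-log
    time, optionally with additive noise (sd = noise_frac * peak value)."""
    x = grid.log_centers
    y = np.zeros_like(x)
    for a, mu, sigma in components:
        y = y + a * np.exp(-((x - math.log(mu)) ** 2) / (2.0 * sigma**2))
    if noise_frac > 0.0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_frac * y.max(), x.size), 0.0, None)
    return DRTResult(grid, y * grid.bin_width_logtau, R_inf)
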