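"""Core domain types for relaxation-time analysis of impedance spectra.

An impedance spectrum Z(omega) measured over a frequency sweep is modelled as a
superposition of first-order (Debye) relaxations,

    Z(omega) = R_inf + R_p * integral g(tau) / (1 + j*omega*tau) dtau,

with ``integral g(tau) dtau = 1``.  Because relaxation times in tissue span many
decades, the distribution is analysed on a logarithmic time axis through
``G(log tau) = tau * g(tau)``; the change of variables x = log(tau) is exact in
the NATURAL logarithm (``G(x) dx = g(tau) dtau``), so every internal log-tau
axis in this package is base e.  Base-10 labelling is a display concern only.

The types below are deliberately thin containers with validated invariants;
all numerics live in :mod:`tissuedrt.inversion`, :mod:`tissuedrt.decompose`
and friends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ValidationError",
    "ImpedanceSpectrum",
    "RelaxationGrid",
    "DRTResult",
    "GaussianComponent",
    "DecompositionModel",
]


class ValidationError(ValueError):
    """A domain invariant was violated when constructing or loading an object."""


@dataclass
class ImpedanceSpectrum:
    """A measured (or simulated) impedance spectrum.

    Parameters
    ----------
    frequencies:
        Strictly increasing frequencies in Hz.
    impedance:
        Complex impedance in ohms at each frequency.  Capacitive points carry a
        negative imaginary part (spectra are stored as measured; instruments
        exporting -Im(Z) are handled by the reader's dialect flag).
    meta:
        Free-form provenance: sample id, field amplitude in V/cm, pre/post
        flag, RMS drive voltage, sign convention used on read, ...
    """

    frequencies: np.ndarray
    impedance: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.ndim != 1:
            raise ValidationError("frequencies must be one-dimensional")
        if self.frequencies.size != self.impedance.size:
            raise ValidationError(
                f"impedance length {self.impedance.size} does not match "
                f"frequency length {self.frequencies.size}"
            )
        if self.frequencies.size < 1:
            raise ValidationError("a spectrum needs at least 1 point")
        if np.any(self.frequencies <= 0):
            raise ValidationError("frequencies must be strictly positive")
        df = np.diff(self.frequencies)
        if np.any(df == 0):
            raise ValidationError("duplicate frequencies in spectrum")
        if np.any(df < 0):
            raise ValidationError("frequencies must be strictly increasing")
        if self.frequencies.size < 8:
            warnings.warn(
                f"spectrum has only {self.frequencies.size} points; "
                "inversions on so few frequencies are poorly constrained",
                stacklevel=2,
            )
        if np.any(self.impedance.real <= 0):
            warnings.warn(
                "spectrum contains non-positive real parts; "
                "physical tissue spectra have Re(Z) > 0",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return int(self.frequencies.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.frequencies

    def rescaled(self, factor: float) -> "ImpedanceSpectrum":
        """Return a copy with every impedance multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("rescale factor must be positive")
        meta = dict(self.meta)
        meta["rescale_factor"] = factor * meta.get("rescale_factor", 1.0)
        return ImpedanceSpectrum(self.frequencies.copy(), self.impedance * factor, meta)


@dataclass(frozen=True)
class RelaxationGrid:
    """Uniform grid in natural-log relaxation time on [tau_inf, tau_sup].

    The distribution is discretized into ``M`` step functions of equal width in
    log(tau); bin ``j`` is represented by its log-midpoint ``centers[j]``.
    """

    tau_inf: float
    tau_sup: float
    M: int

    #: Default bounds and resolution used for tissue spectra acquired between
    #: 20 Hz and 400 kHz: 120 bins on tau in [1e-7, 10^-1.5] s.
    DEFAULT_TAU_INF = 1e-7
    DEFAULT_TAU_SUP = 10.0 ** -1.5
    DEFAULT_M = 120

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_inf < self.tau_sup):
            raise ValidationError("need 0 < tau_inf < tau_sup")
        if self.M < 10:
            raise ValidationError("grid needs at least 10 bins")

    @classmethod
    def default(cls) -> "RelaxationGrid":
        return cls(cls.DEFAULT_TAU_INF, cls.DEFAULT_TAU_SUP, cls.DEFAULT_M)

    @property
    def bin_width_logtau(self) -> float:
        """Bin width Delta x in natural-log tau (dimensionless)."""
        return math.log(self.tau_sup / self.tau_inf) / self.M

    @property
    def log_edges(self) -> np.ndarray:
        return np.linspace(math.log(self.tau_inf), math.log(self.tau_sup), self.M + 1)

    @property
    def log_centers(self) -> np.ndarray:
        e = self.log_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def centers(self) -> np.ndarray:
        """Bin-center relaxation times tau_j in seconds (log-spaced)."""
        return np.exp(self.log_centers)

    def contains(self, tau: float) -> bool:
        return self.tau_inf < tau < self.tau_sup


@dataclass
class DRTResult:
    """A discretized distribution of relaxation times.

    ``weights[j]`` is the resistance mass carried by bin j, i.e.
    ``R_p * G(x_j) * Delta x`` in ohms, so the polarization resistance is the
    plain sum of the weights and the displayed curve ``R_p * G(x)`` is
    ``weights / bin_width_logtau``.
    """

    grid: RelaxationGrid
    weights: np.ndarray
    R_inf: float
    lambda_reg: float = float("nan")
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != self.grid.M:
            raise ValidationError(
                f"{self.weights.size} weights for a grid of {self.grid.M} bins"
            )
        if np.any(self.weights < 0):
            raise ValidationError("DRT weights must be nonnegative")
        if self.R_inf < 0:
            raise ValidationError("R_inf must be nonnegative")

    @property
    def R_p(self) -> float:
        """Total polarization resistance (ohms); the sum of the bin weights."""
        return float(self.weights.sum())

    @property
    def R_0(self) -> float:
        """DC resistance R_inf + R_p (ohms)."""
        return self.R_inf + self.R_p

    @property
    def curve(self) -> np.ndarray:
        """The distribution ``R_p * G(x)`` sampled at the bin centers (ohms
        per natural-log-tau unit)."""
        return self.weights / self.grid.bin_width_logtau

    def scaled(self, factor: float) -> "DRTResult":
        """Multiply all resistances (weights and R_inf) by ``factor``."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return DRTResult(
            self.grid,
            self.weights * factor,
            self.R_inf * factor,
            self.lambda_reg,
            self.residual_norm * factor,
        )


SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component of ``R_p * G(x)`` in natural-log time.

    The component contributes ``a * exp(-(x - log mu)^2 / (2 sigma^2))`` to the
    displayed distribution; equivalently a log-normal contribution to g(tau).
    Its DC-resistance contribution is the area under the Gaussian,
    ``R_pk = a * sigma * sqrt(2 pi)``.
    """

    a: float      # peak amplitude (ohms per natural-log-tau unit)
    mu: float     # location: mean relaxation time (s)
    sigma: float  # spread in natural-log tau (dimensionless)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("amplitude a must be positive")
        if self.mu <= 0:
            raise ValidationError("mu must be a positive time in seconds")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def R_pk(self) -> float:
        """DC-resistance contribution of this component (ohms)."""
        return self.a * self.sigma * SQRT_2PI

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Component value on a natural-log-tau axis ``x``."""
        return self.a * np.exp(-((x - math.log(self.mu)) ** 2) / (2.0 * self.sigma**2))


@dataclass
class DecompositionModel:
    """A K-Gaussian model of a tissue DRT, ordered by decreasing mu.

    The ordering convention mirrors the physical reading of the DC expansion
    R_0 = R_inf + sum_k R_pk: as frequency decreases, relaxation processes
    reach steady state from component K (shortest time) up to component 1,
    each adding its R_pk to the observed resistance.
    """

    components: list[GaussianComponent]
    R_inf: float
    rss: float = float("nan")
    n: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("decomposition needs at least one component")
        self.components = sorted(self.components, key=lambda c: -c.mu)
        mus = [c.mu for c in self.components]
        if any(m1 <= m2 for m1, m2 in zip(mus, mus[1:])):
            raise ValidationError("component locations mu must be distinct")
        if self.R_inf < 0:
            raise ValidationError("R_inf must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def R_pks(self) -> np.ndarray:
        return np.array([c.R_pk for c in self.components])

    @property
    def R_0(self) -> float:
        """DC resistance R_inf + sum_k R_pk (ohms), recomputed on access."""
        return self.R_inf + float(self.R_pks.sum())

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Model curve ``R_p * G(x)`` on a natural-log-tau axis ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.evaluate(x)
        return out
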