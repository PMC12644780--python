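"""Order-of-magnitude thermal side-calculations for pulse protocols.

Electroporation pulses deposit Joule heat in the sample.  These helpers bound
the resulting temperature rise and its effect on conductivity so that
impedance changes can be attributed to membrane effects rather than heating:

* absorbed energy U * I * (n * pulse duration) for rectangular pulses;
* sample heat capacity rho * c_p * V for a cylindrical sample;
* the ADIABATIC temperature rise E / C - an upper bound, since conduction
  through the electrodes removes heat;
* thermal diffusion time l^2 rho c_p / k, to judge how much cooling happens
  before the post-pulse spectrum is acquired;
* the relative conductivity change alpha_T * dT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ValidationError

__all__ = [
    "PulseProtocol",
    "SampleThermal",
    "ESOPE",
    "absorbed_energy",
    "heat_capacity",
    "adiabatic_rise",
    "diffusion_time",
    "conductivity_change",
]


@dataclass(frozen=True)
class PulseProtocol:
    """A train of rectangular pulses.

    U: pulse voltage (V); I: current during the pulse (A); n_pulses: count;
    pulse_duration and period in seconds; field: nominal field (V/cm),
    informational only.
    """

    U: float
    I: float
    n_pulses: int
    pulse_duration: float
    period: float = 1.0
    field: float = 0.0

    def __post_init__(self) -> None:
        for name in ("U", "I", "n_pulses", "pulse_duration", "period"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.pulse_duration >= self.period:
            raise ValidationError("pulse_duration must be shorter than the period")


def ESOPE(U: float, I: float, field: float = 0.0) -> PulseProtocol:
    """The standard electrochemotherapy train: 8 rectangular 100 us pulses
    separated by 1 s."""
    return PulseProtocol(U, I, 8, 100e-6, 1.0, field)


@dataclass(frozen=True)
class SampleThermal:
    """Thermal properties of a cylindrical tissue sample.

    rho kg/m^3; c_p J/(kg K); k_th W/(m K); diameter and height in m;
    alpha_T 1/K, the relative conductivity change per kelvin (0.025-0.03/K
    for intact to fully damaged potato tissue).
    """

    rho: float = 1062.0
    c_p: float = 3770.0
    k_th: float = 0.55
    diameter: float = 10e-3
    height: float = 4.5e-3
    alpha_T: float = 0.025

    def __post_init__(self) -> None:
        for name in ("rho", "c_p", "k_th", "diameter", "height", "alpha_T"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2 * self.height


def absorbed_energy(protocol: PulseProtocol) -> float:
    """Joule energy deposited by the train: U * I * cumulative pulse time (J)."""
    return protocol.U * protocol.I * protocol.n_pulses * protocol.pulse_duration


def heat_capacity(sample: SampleThermal) -> float:
    """Heat capacity rho * c_p * V of the cylindrical sample (J/K)."""
    return sample.rho * sample.c_p * sample.volume


def adiabatic_rise(energy: float, capacity: float) -> float:
    """Adiabatic UPPER BOUND on the temperature rise, E / C (K).

    The real rise is lower: heat leaves through the electrodes while and
    after the pulses are applied.
    """
    if capacity <= 0:
        raise ValidationError("heat capacity must be positive")
    return energy / capacity


def diffusion_time(length: float, sample: SampleThermal) -> float:
    """Thermal diffusion time l^2 rho c_p / k over a characteristic length
    (s); use half the sample height for electrode-sandwiched samples."""
    if length <= 0:
        raise ValidationError("characteristic length must be positive")
    return length**2 * sample.rho * sample.c_p / sample.k_th


def conductivity_change(alpha_T: float, dT: float) -> float:
    """Relative conductivity change alpha_T * dT (dimensionless fraction)."""
    return alpha_T * dT
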