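"""External electric-field waveforms and their surface forcing.

Three spatially uniform field waveforms are studied:

* ``PDCEF`` — pulsed DC field along x: E0 * xhat during the first ``d`` time
  units of every period 2*pi/omega_e, zero otherwise.
* ``ACEF``  — alternating field along x: E0 * cos(omega_e t) * xhat.
* ``CPEF``  — circularly polarized field rotating in the xy-plane:
  E0 * (cos(omega_e t), sin(omega_e t), 0); constant magnitude E0.

The field enters the medium only through the Neumann condition on the
obstacle surface, n . grad(u) = n . E, with n the outward obstacle normal
n = (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)).  The surface
forcing n . E therefore has extremum E0 sin(theta) |cos(phi)| for the
x-directed waveforms (dependent on both angles) but E0 sin(theta) for the
rotating field (azimuth-independent), which is why the rotating field acts
on the whole equator of a spherical obstacle rather than two poles of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class FieldKind(str, Enum):
    NONE = "none"
    PDCEF = "pdcef"
    ACEF = "acef"
    CPEF = "cpef"


# integer codes used by the compiled stepping kernel
_KIND_CODE = {FieldKind.NONE: 0, FieldKind.PDCEF: 1, FieldKind.ACEF: 2, FieldKind.CPEF: 3}


@dataclass(frozen=True)
class FieldSpec:
    """Waveform kind, amplitude E0, angular frequency omega_e and (for the
    pulsed field) pulse duration ``d``; ``phase`` is the initial phase of
    the oscillatory waveforms."""

    kind: FieldKind = FieldKind.NONE
    E0: float = 0.0
    omega_e: float = 1.0
    pulse_duration: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        kind = FieldKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.E0 < 0:
            raise ValueError("E0 must be non-negative")
        if kind in (FieldKind.PDCEF, FieldKind.ACEF, FieldKind.CPEF) and self.omega_e <= 0:
            raise ValueError("omega_e must be positive for a time-varying field")
        if kind is FieldKind.PDCEF:
            if not (0.0 < self.pulse_duration < 2.0 * math.pi / self.omega_e):
                raise ValueError("PDCEF pulse duration must lie in (0, period)")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega_e

    @property
    def kind_code(self) -> int:
        return _KIND_CODE[self.kind]

    @staticmethod
    def none() -> "FieldSpec":
        return FieldSpec(kind=FieldKind.NONE)

    @staticmethod
    def pdcef(E0: float, omega_e: float, pulse_duration: float) -> "FieldSpec":
        return FieldSpec(FieldKind.PDCEF, E0, omega_e, pulse_duration)

    @staticmethod
    def acef(E0: float, omega_e: float) -> "FieldSpec":
        return FieldSpec(FieldKind.ACEF, E0, omega_e)

    @staticmethod
    def cpef(E0: float, omega_e: float) -> "FieldSpec":
        return FieldSpec(FieldKind.CPEF, E0, omega_e)


def field_vector(spec: FieldSpec, t: float) -> tuple[float, float, float]:
    """Spatially uniform field vector E(t)."""
    if spec.kind is FieldKind.NONE or spec.E0 == 0.0:
        return (0.0, 0.0, 0.0)
    if spec.kind is FieldKind.PDCEF:
        t_in_period = math.fmod(t, spec.period)
        if t_in_period < 0.0:
            t_in_period += spec.period
        on = t_in_period < spec.pulse_duration
        return (spec.E0 if on else 0.0, 0.0, 0.0)
    wt = spec.omega_e * t + spec.phase
    if spec.kind is FieldKind.ACEF:
        return (spec.E0 * math.cos(wt), 0.0, 0.0)
    # CPEF: rotates about z, |E| = E0 at all times
    return (spec.E0 * math.cos(wt), spec.E0 * math.sin(wt), 0.0)


def surface_forcing(spec: FieldSpec, theta: float, phi_az: float, t: float) -> float:
    """n . E on the spherical obstacle surface at polar angle ``theta`` and
    azimuth ``phi_az`` at time ``t``."""
    ex, ey, _ez = field_vector(spec, t)
    st = math.sin(theta)
    return st * (math.cos(phi_az) * ex + math.sin(phi_az) * ey)


def surface_forcing_extremum(spec: FieldSpec, theta: float, phi_az: float) -> float:
    """max over t of |n . E| at a surface point.

    x-directed waveforms: E0 sin(theta) |cos(phi_az)|; rotating field:
    E0 sin(theta), independent of azimuth.
    """
    st = abs(math.sin(theta))
    if spec.kind is FieldKind.NONE:
        return 0.0
    if spec.kind is FieldKind.CPEF:
        return spec.E0 * st
    return spec.E0 * st * abs(math.cos(phi_az))
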