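"""Physical constants and magnetic-field specification.

All quantities are SI. The defaults are the material constants of the
tubulin/microtubule system: the diamagnetic-anisotropy volume of a tubulin
dimer, the dimer length, the zero-field polymerization speed, the flexural
rigidity of a microtubule, and the rotational drag per unit filament
length, together with the rearing temperature of zebrafish embryos
(28.5 degC = 301.65 K).

Two printed literature values are dimensionally ambiguous and are resolved
here once, with the reading exposed as a plain configurable field:

* ``EI`` — flexural rigidity is taken as 33.12 pN um^2 = 3.312e-23 N m^2,
  the standard magnitude for a single microtubule (taking the printed
  "pN m^2" literally would make magnetic bending immeasurably small and
  remove the dominant mechanism of the model).
* ``xi`` — the per-unit-length drag "1 pNs/nm" is read as
  xi = 1e-3 N s/m^2 so that xi * L^2 has units N s m and the rigid-rod
  rotation rate 2M/(xi L^2) comes out in rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any, Mapping

from .errors import InvalidFieldError

__all__ = ["PhysicalConstants", "FieldSpec"]


@dataclass(frozen=True)
class PhysicalConstants:
    """Material constants of the microtubule system, SI units.

    Attributes
    ----------
    delta_chi : float
        Diamagnetic-anisotropy volume of one tubulin dimer, m^3.
    mu0 : float
        Vacuum permeability, T m / A.
    kB : float
        Boltzmann constant, J / K.
    T_abs : float
        Absolute temperature, K.  Default is 301.65 K (28.5 degC).
    d0 : float
        Length of one tubulin dimer along the protofilament, m.
    EI : float
        Flexural rigidity of a microtubule, N m^2.
    xi : float
        Rotational drag coefficient per unit filament length, N s / m^2.
    v0 : float
        Zero-field polymerization speed, m / s.
    """

    delta_chi: float = 1.243e-32
    mu0: float = 4.0e-7 * math.pi
    kB: float = 1.380649e-23
    T_abs: float = 301.65
    d0: float = 8.0e-9
    EI: float = 3.312e-23
    xi: float = 1.0e-3
    v0: float = 1.25e-7

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"PhysicalConstants.{f.name} must be finite and > 0, got {value!r}")

    @property
    def thermal_energy(self) -> float:
        """k_B * T, J."""
        return self.kB * self.T_abs

    def replace(self, **changes: float) -> "PhysicalConstants":
        return replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PhysicalConstants":
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class FieldSpec:
    """Homogeneous static magnetic field.

    Attributes
    ----------
    B : float
        Magnetic flux density, T.  ``B = 0`` disables every magnetic
        term exactly.
    direction_angle : float
        Lab-frame direction of the field, rad.  The simulator's default
        places the field along the cell's short axis (pi/2).
    """

    B: float = 0.0
    direction_angle: float = math.pi / 2

    def __post_init__(self) -> None:
        if not (math.isfinite(self.B) and self.B >= 0):
            raise InvalidFieldError(f"magnetic flux density must be >= 0, got {self.B!r}")
        if not math.isfinite(self.direction_angle):
            raise InvalidFieldError("field direction_angle must be finite")

    @property
    def off(self) -> bool:
        return self.B == 0.0

    def to_dict(self) -> dict:
        return {"B": self.B, "direction_angle": self.direction_angle}
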