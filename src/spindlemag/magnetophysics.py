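"""Closed-form magneto-mechanics of tubulin dimers and microtubules.

A tubulin dimer is diamagnetically anisotropic: its magnetizability along
the alpha-beta axis differs from the orthogonal axes by the volume
``delta_chi``.  In a homogeneous static field B the dimer therefore feels
an orientation-dependent torque and energy, which (i) biases the
Boltzmann orientation distribution of dissociative dimers and hence the
polymerization speed at a growing tip, (ii) rotates whole filaments
toward the field axis against viscous drag, and (iii) — because the
torque is distributed along the filament — bends a pole-anchored
microtubule like a cantilever under a distributed moment, which in turn
reduces the pulling force it can transmit.

All functions here are pure, vectorized over their angular/length
arguments, and work in SI units.  ``theta`` is always the angle between
the dimer/filament axis and the field direction; every quantity has
period pi in ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import FieldSpec, PhysicalConstants
from .errors import DegenerateBendingError, DomainError, InvalidGeometryError

__all__ = [
    "DeflectionProfile",
    "dimer_torque",
    "dimer_orientation_energy",
    "dimer_orientation_pdf",
    "polymerization_rate",
    "mt_torque",
    "mt_rotation_rate",
    "bending_moment",
    "deflection",
    "max_deflection",
    "effective_pulling_force",
    "PROTOFILAMENTS",
]

#: Number of protofilaments in a standard microtubule; a filament of
#: length L contains PROTOFILAMENTS * L / d0 dimers.
PROTOFILAMENTS = 13


def _field_energy_scale(field: FieldSpec, consts: PhysicalConstants) -> float:
    """delta_chi * B^2 / (2 mu0): torque/energy scale of one dimer, J."""
    return consts.delta_chi * field.B**2 / (2.0 * consts.mu0)


def dimer_torque(theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Magnetic torque on a single tubulin dimer, N m.

    M0(theta) = (delta_chi B^2 / 2 mu0) sin(2 theta).  Positive torque
    rotates the dimer toward field alignment; it vanishes at theta = 0
    and theta = pi/2 and is maximal at pi/4.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DomainError("theta must be finite")
    if field.off:
        return np.zeros_like(theta)[()] if theta.shape == () else np.zeros_like(theta)
    out = _field_energy_scale(field, consts) * np.sin(2.0 * theta)
    return out[()] if out.shape == () else out


def dimer_orientation_energy(theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Orientation energy of a dimer at angle theta to the field, J.

    E(theta) = (delta_chi B^2 / 2 mu0) sin^2(theta); dE/dtheta equals
    :func:`dimer_torque`.  Zero for a field-aligned dimer.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DomainError("theta must be finite")
    if field.off:
        return np.zeros_like(theta)[()] if theta.shape == () else np.zeros_like(theta)
    out = _field_energy_scale(field, consts) * np.sin(theta) ** 2
    return out[()] if out.shape == () else out


def dimer_orientation_pdf(
    theta,
    field: FieldSpec,
    consts: PhysicalConstants = PhysicalConstants(),
    support: str = "planar",
):
    """Boltzmann orientation density of dissociative dimers, 1/rad.

    p(theta) = k0 exp(-E(theta) / kB T), with k0 fixed by numerical
    normalization over the chosen support.

    ``support="planar"`` (default) normalizes over theta in
    [-pi/2, pi/2), matching the planar spindle simulator.
    ``support="spherical"`` weights by sin(theta) on [0, pi] for a
    3-D axisymmetric dimer orientation.
    """
    theta = np.asarray(theta, dtype=float)
    kT = consts.thermal_energy
    scale = _field_energy_scale(field, consts)

    if support == "planar":
        def unnorm(t):
            return np.exp(-scale * np.sin(t) ** 2 / kT)

        norm, _ = quad(unnorm, -np.pi / 2, np.pi / 2, epsabs=1e-14, epsrel=1e-12)
        out = unnorm(theta) / norm
    elif support == "spherical":
        def unnorm(t):
            return np.sin(t) * np.exp(-scale * np.sin(t) ** 2 / kT)

        norm, _ = quad(unnorm, 0.0, np.pi, epsabs=1e-14, epsrel=1e-12)
        out = unnorm(theta) / norm
    else:
        raise DomainError(f"unknown support {support!r}; use 'planar' or 'spherical'")
    out = np.asarray(out)
    return out[()] if out.shape == () else out


def polymerization_rate(theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Polymerization speed of a tip growing at angle theta to the field, m/s.

    v(theta) = v0 exp(-delta_chi B^2 sin^2(theta) / (2 mu0 kB T)).

    Equals v0 exactly for growth parallel to the field (or at B = 0) and
    is smallest for growth perpendicular to it: the field orients the
    dissociative dimer pool, depleting the sub-population correctly
    oriented for addition onto obliquely growing tips.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DomainError("theta must be finite")
    if field.off:
        out = np.full_like(theta, consts.v0)
        return out[()] if out.shape == () else out
    out = consts.v0 * np.exp(-_field_energy_scale(field, consts) * np.sin(theta) ** 2 / consts.thermal_energy)
    return out[()] if out.shape == () else out


def _check_length(L) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L) & (L > 0)):
        raise InvalidGeometryError(f"microtubule length must be finite and > 0, got {L!r}")
    return L


def mt_torque(L, theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Total magnetic torque on a rigid microtubule of length L, N m.

    The filament contains 13 L / d0 dimers, each contributing
    :func:`dimer_torque`, so M = (13 L / d0) (delta_chi B^2 / 2 mu0)
    sin(2 theta) — strictly proportional to L.
    """
    L = _check_length(L)
    n_dimers = PROTOFILAMENTS * L / consts.d0
    out = n_dimers * dimer_torque(theta, field, consts)
    out = np.asarray(out)
    return out[()] if out.shape == () else out


def mt_rotation_rate(L, theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Angular speed of a rigid microtubule rotating under the magnetic
    torque against viscous drag, rad/s.

    phi_dot = 2 M / (xi L^2), with xi the drag coefficient per unit
    length.  Positive values rotate the filament toward field alignment
    (theta decreasing toward 0 on (0, pi/2); the returned value is
    negative on (pi/2, pi), i.e. toward anti-parallel alignment, which is
    the same physical axis).  Maximal over theta at pi/4.
    """
    L = _check_length(L)
    out = 2.0 * mt_torque(L, theta, field, consts) / (consts.xi * L**2)
    out = np.asarray(out)
    return out[()] if out.shape == () else out


def bending_moment(x, L, theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Internal bending moment at arclength x from the anchored minus end, N m.

    The magnetic torque is distributed along the filament; the moment
    carried by the cross-section at x is the integral of the torque
    density over the portion beyond x:

    M(x) = (13 delta_chi B^2 / 2 d0 mu0) (L - x) sin(2 theta),

    zero at the free tip x = L and maximal at the anchored end x = 0.
    """
    L = _check_length(L)
    x = np.asarray(x, dtype=float)
    if not np.all((x >= 0) & (x <= L)):
        raise DomainError("x must lie in [0, L]")
    if field.off:
        out = np.zeros(np.broadcast(x, L).shape)
        return out[()] if out.shape == () else out
    coeff = PROTOFILAMENTS * consts.delta_chi * field.B**2 / (2.0 * consts.d0 * consts.mu0)
    out = coeff * (L - x) * np.sin(2.0 * np.asarray(theta, dtype=float))
    out = np.asarray(out)
    return out[()] if out.shape == () else out


@dataclass(frozen=True)
class DeflectionProfile:
    """Cantilever deflection of a pole-anchored microtubule under the
    distributed magnetic moment.

    Attributes
    ----------
    x : ndarray
        Arclength positions from the anchored end, m, 0 <= x <= L.
    moment : ndarray
        Internal bending moment M(x), N m.
    omega : ndarray
        Transverse deflection omega(x), m (clamped end: omega(0) =
        omega'(0) = 0).
    omega_max : float
        Tip deflection omega(L), the profile maximum, m.
    """

    x: np.ndarray
    moment: np.ndarray
    omega: np.ndarray
    omega_max: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x_m": self.x, "moment_Nm": self.moment, "deflection_m": self.omega})


def _deflection_coefficient(theta, field: FieldSpec, consts: PhysicalConstants) -> np.ndarray:
    """13 delta_chi B^2 |sin 2theta| / (2 d0 mu0 EI), 1/m^2."""
    return (
        PROTOFILAMENTS
        * consts.delta_chi
        * field.B**2
        * np.abs(np.sin(2.0 * np.asarray(theta, dtype=float)))
        / (2.0 * consts.d0 * consts.mu0 * consts.EI)
    )


def deflection(
    L: float,
    theta: float,
    field: FieldSpec,
    consts: PhysicalConstants = PhysicalConstants(),
    n_points: int = 201,
) -> DeflectionProfile:
    """Small-deformation beam deflection under the distributed magnetic
    moment, for a filament clamped at the spindle pole.

    omega(x) = [13 delta_chi B^2 sin(2 theta) / (2 d0 mu0 EI)]
               (L x^2 / 2 - x^3 / 6),

    the double integral of :func:`bending_moment` / EI with clamped
    boundary conditions.  The tip deflection omega_max = omega(L) =
    coefficient * L^3 / 3 scales as L^3 and B^2.  The profile stores the
    deflection magnitude (toward the field axis).
    """
    L = float(_check_length(L))
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    x = np.linspace(0.0, L, int(n_points))
    if field.off:
        zeros = np.zeros_like(x)
        return DeflectionProfile(x=x, moment=zeros, omega=zeros.copy(), omega_max=0.0)
    k = float(_deflection_coefficient(theta, field, consts))
    sgn = np.sign(np.sin(2.0 * float(theta))) or 1.0
    moment = np.asarray(bending_moment(x, L, theta, field, consts)) * sgn  # magnitude
    omega = k * (0.5 * L * x**2 - x**3 / 6.0)
    return DeflectionProfile(x=x, moment=moment, omega=omega, omega_max=float(omega[-1]))


def max_deflection(L, theta, field: FieldSpec, consts: PhysicalConstants = PhysicalConstants()):
    """Tip deflection magnitude omega_max = coefficient * L^3 / 3, m.

    Closed form used per-filament per-step by the simulator; equals
    ``deflection(...).omega_max``.
    """
    L = _check_length(L)
    if field.off:
        out = np.zeros(np.broadcast(L, np.asarray(theta, dtype=float)).shape)
        return out[()] if out.shape == () else out
    out = _deflection_coefficient(theta, field, consts) * L**3 / 3.0
    out = np.asarray(out)
    return out[()] if out.shape == () else out


def effective_pulling_force(f_c, L, omega_max):
    """Pulling force transmitted by a bent microtubule, same units as f_c.

    A filament of arclength L whose tip is deflected by omega_max spans
    an axial extent of only sqrt(L^2 - omega_max^2); the force a
    tip-to-pole motor can transmit along the spindle axis is reduced by
    that chord projection:

    f* = f_c sqrt(L^2 - omega_max^2) / L.

    Always <= f_c, with equality iff omega_max = 0; tends to 0 as
    omega_max -> L.  Callers must clamp omega_max below L first (the
    small-deformation formula can formally exceed it for very long
    filaments).
    """
    f_c = np.asarray(f_c, dtype=float)
    L = _check_length(L)
    omega_max = np.asarray(omega_max, dtype=float)
    if np.any(f_c < 0):
        raise DomainError("f_c must be >= 0")
    if np.any(omega_max < 0):
        raise DomainError("omega_max must be >= 0")
    if np.any(omega_max >= L):
        raise DegenerateBendingError("omega_max >= L: clamp deflection before projecting the force")
    out = f_c * np.sqrt(L**2 - omega_max**2) / L
    out = np.asarray(out)
    return out[()] if out.shape == () else out
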