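"""Monte Carlo simulation of spindle positioning in an elliptical cell.

The model: astral microtubules are nucleated at the two spindle poles,
grow radially outward and display dynamic instability (stochastic
catastrophe/rescue switching between growth and shrinkage).  Each
filament pulls its pole with a force proportional to its length
(cytoplasmic motor pulling); filaments whose tip reaches the cortex
additionally push by polymerization and, stochastically, pull via
cortical dynein.  Length-proportional pulling against the cell boundary
centers the spindle, and the boundary anisotropy of an elliptical cell
orients it along the long axis.  The spindle is a rigid body moving
overdamped: center_dot = F / Gamma_t, alpha_dot = tau / Gamma_r.

A static magnetic field enters through three pathways, each of which can
be ablated independently:

* ``rate`` — the tip growth speed is modulated by the Boltzmann-biased
  dimer pool (anisotropic polymerization rate);
* ``rotation`` — filaments rotate toward the field axis at the rigid-rod
  rate, and the net rigid-rod magnetic torque acts on the spindle body;
* ``bending`` — each filament is deflected like a cantilever under the
  distributed magnetic moment, and every pulling force it transmits is
  attenuated by the chord projection sqrt(L^2 - omega_max^2)/L.  (An
  optional ``bending_redirect`` mode additionally rotates the pull along
  the pole-to-deflected-tip chord; it is off by default because steering
  every pull toward the field axis actively re-orients the spindle,
  which contradicts the observed slowdown of orientation.)

Internal unit system: um, s, pN (drags in pN s/um and pN s um).  The
magneto-physics functions are SI; conversions happen at this module's
boundary only.

Nucleation directions are uniform on [0, 2pi).  By default they are
*stratified* (one direction per equal angular bin, uniform within the
bin): a computational aster of 50-200 filaments stands in for a real
aster of thousands, and stratification removes the spurious static
polarity (~ 1/sqrt(n_mt) resultant) that independent sampling would
imprint on so few filaments.  Independent sampling is available with
``nucleation="iid"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, fields, replace
from typing import Optional, Sequence

import numpy as np

from .constants import FieldSpec, PhysicalConstants
from .errors import InstabilityError, InvalidGeometryError, TimestepError
from .geometry import CellGeometry, SpindleState
from .magnetophysics import PROTOFILAMENTS

__all__ = [
    "Microtubule",
    "DynamicInstabilityParams",
    "ForceParams",
    "SimConfig",
    "Trajectory",
    "nucleate_ensemble",
    "step_microtubule",
    "net_wrench",
    "simulate",
    "run_ensemble",
    "ensemble_mean",
]

_GROWING, _SHRINKING = 1, 0


@dataclass
class Microtubule:
    """One astral microtubule (scalar view of the internal arrays).

    ``psi`` is the lab-frame growth direction from the anchoring pole,
    ``L`` the arclength in um.  ``at_cortex`` marks tips within the
    contact tolerance of the cell boundary; ``clamped_bend`` marks
    filaments whose small-deformation deflection had to be clamped
    below L.
    """

    pole_id: int
    psi: float
    L: float = 0.0
    state: str = "growing"
    at_cortex: bool = False
    clamped_bend: bool = False
    stratum: int = -1  # nucleation bin for stratified resampling; -1 = iid


@dataclass(frozen=True)
class DynamicInstabilityParams:
    """Two-state tip dynamics, um and s.

    Defaults give net-growing filaments (v_g f_res > v_s f_cat) so that
    asters span the several-hundred-um blastomere, as they must to
    position its spindle; v_g is the zero-field polymerization speed of
    the tubulin system (0.125 um/s).
    """

    v_g: float = 0.125
    v_s: float = 0.25
    f_cat: float = 0.002
    f_res: float = 0.04

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ForceParams:
    """Force and drag coefficients of the reference positioning model.

    alpha_cyto : pN per um of filament (cytoplasmic length-proportional
    pulling); f_push : cortical polymerization push, pN; f_dyn : cortical
    dynein pull, pN; p_bind : dynein binding probability per contact per
    step; Gamma_t, Gamma_r : translational / rotational drag of the
    spindle, pN s/um and pN s um.
    """

    alpha_cyto: float = 0.01
    f_push: float = 1.0
    f_dyn: float = 2.0
    p_bind: float = 0.1
    Gamma_t: float = 100.0
    Gamma_r: float = 1.0e5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.Gamma_t == 0 or self.Gamma_r == 0:
            raise ValueError("drag coefficients must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SimConfig:
    """Run-level configuration.

    ``stride`` controls trajectory sampling (every ``stride``-th step is
    recorded, plus the initial and final states).  The ``enable_*`` flags
    ablate individual magnetic pathways for mechanism attribution.

    ``init_mt`` selects the initial aster: ``"zero"`` nucleates
    zero-length filaments (the aster grows in during the run);
    ``"spanning"`` starts every filament truncated at the cortex, the
    steady state of net-growing dynamics, which models relaxation of a
    spindle whose aster is already established at mitosis onset.
    """

    dt: float = 0.5
    t_max: float = 6000.0
    n_mt: int = 100
    seed: int = 0
    field: FieldSpec = dc_field(default_factory=lambda: FieldSpec(0.0))
    ensemble_n: int = 20
    stride: int = 10
    nucleation: str = "stratified"
    init_mt: str = "zero"
    contact_tol: float = 0.5
    enable_rate: bool = True
    enable_rotation: bool = True
    enable_bending: bool = True
    bending_redirect: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_max < self.dt:
            raise ValueError("t_max must be >= dt")
        if self.n_mt < 1:
            raise ValueError("n_mt must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.nucleation not in ("stratified", "iid"):
            raise ValueError(f"unknown nucleation mode {self.nucleation!r}")
        if self.init_mt not in ("zero", "spanning"):
            raise ValueError(f"unknown init_mt mode {self.init_mt!r}")

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["field"] = self.field.to_dict()
        return d


@dataclass
class Trajectory:
    """Time series of one simulation run.

    ``t`` in s; ``d`` the center offset |center| in um; ``alpha`` the
    orientation angle in rad.  ``meta`` carries the resolved seed, field
    and geometry for provenance.
    """

    t: np.ndarray
    d: np.ndarray
    alpha: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (self.t.shape == self.d.shape == self.alpha.shape):
            raise ValueError("t, d, alpha must have equal shapes")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.d < 0):
            raise ValueError("offsets must be >= 0")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.t, "d_um": self.d, "alpha_rad": self.alpha})


# ---------------------------------------------------------------------------
# internal array-of-structs representation


class _MTArrays:
    """Vectorized microtubule ensemble; one entry per filament."""

    __slots__ = ("pole_id", "psi", "L", "growing", "at_cortex", "clamped", "stratum", "n_per_pole")

    def __init__(self, pole_id, psi, L, growing, at_cortex, clamped, stratum, n_per_pole):
        self.pole_id = pole_id
        self.psi = psi
        self.L = L
        self.growing = growing
        self.at_cortex = at_cortex
        self.clamped = clamped
        self.stratum = stratum
        self.n_per_pole = n_per_pole

    @classmethod
    def nucleate(cls, n_per_pole: int, mode: str, rng: np.random.Generator) -> "_MTArrays":
        n = 2 * n_per_pole
        pole_id = np.repeat(np.array([0, 1]), n_per_pole)
        if mode == "stratified":
            strata = np.tile(np.arange(n_per_pole), 2)
            u = rng.random(n)
            psi = 2.0 * np.pi * (strata + u) / n_per_pole
        else:
            strata = np.full(n, -1)
            psi = rng.random(n) * 2.0 * np.pi
        return cls(
            pole_id=pole_id,
            psi=np.mod(psi, 2.0 * np.pi),
            L=np.zeros(n),
            growing=np.ones(n, dtype=bool),
            at_cortex=np.zeros(n, dtype=bool),
            clamped=np.zeros(n, dtype=bool),
            stratum=strata,
            n_per_pole=n_per_pole,
        )

    @classmethod
    def from_list(cls, mts: Sequence[Microtubule]) -> "_MTArrays":
        n_per_pole = max(1, sum(1 for m in mts if m.pole_id == 0))
        return cls(
            pole_id=np.array([m.pole_id for m in mts], dtype=int),
            psi=np.array([m.psi for m in mts], dtype=float),
            L=np.array([m.L for m in mts], dtype=float),
            growing=np.array([m.state == "growing" for m in mts], dtype=bool),
            at_cortex=np.array([m.at_cortex for m in mts], dtype=bool),
            clamped=np.array([m.clamped_bend for m in mts], dtype=bool),
            stratum=np.array([m.stratum for m in mts], dtype=int),
            n_per_pole=n_per_pole,
        )

    def to_list(self) -> list:
        return [
            Microtubule(
                pole_id=int(self.pole_id[i]),
                psi=float(self.psi[i]),
                L=float(self.L[i]),
                state="growing" if self.growing[i] else "shrinking",
                at_cortex=bool(self.at_cortex[i]),
                clamped_bend=bool(self.clamped[i]),
                stratum=int(self.stratum[i]),
            )
            for i in range(self.psi.size)
        ]


def _rate_factor(theta_B: np.ndarray, field: FieldSpec, consts: PhysicalConstants) -> np.ndarray:
    """v(theta)/v0 of the anisotropic polymerization rate."""
    scale = consts.delta_chi * field.B**2 / (2.0 * consts.mu0)
    return np.exp(-scale * np.sin(theta_B) ** 2 / consts.thermal_energy)


def _rotation_rate(L_um: np.ndarray, theta_B: np.ndarray, field: FieldSpec, consts: PhysicalConstants) -> np.ndarray:
    """Signed rigid-rod rotation rate toward alignment, rad/s (L in um)."""
    L_m = np.maximum(L_um, 1e-3) * 1e-6
    coeff = PROTOFILAMENTS * consts.delta_chi * field.B**2 / (consts.d0 * consts.mu0 * consts.xi)
    return coeff * np.sin(2.0 * theta_B) / L_m


def _deflection_um(L_um: np.ndarray, theta_B: np.ndarray, field: FieldSpec, consts: PhysicalConstants) -> np.ndarray:
    """Signed tip deflection of the cantilever formula, um (L in um)."""
    L_m = L_um * 1e-6
    coeff = PROTOFILAMENTS * consts.delta_chi * field.B**2 / (2.0 * consts.d0 * consts.mu0 * consts.EI)
    return coeff * np.sin(2.0 * theta_B) * L_m**3 / 3.0 * 1e6


def _step_arrays(
    mt: _MTArrays,
    poles: np.ndarray,
    di: DynamicInstabilityParams,
    field: FieldSpec,
    consts: PhysicalConstants,
    dt: float,
    rng: np.random.Generator,
    geom: CellGeometry,
    cfg: SimConfig,
) -> None:
    """Advance every filament by dt in place.

    Random-stream discipline: exactly two uniform arrays are drawn per
    step regardless of the field, so paired runs that share a seed see
    identical catastrophe/rescue/renucleation randomness whether or not
    the field is on.
    """
    n = mt.psi.size
    u_event = rng.random(n)
    u_renuc = rng.random(n)

    magnetic = (field.B > 0.0)
    theta_B = mt.psi - field.direction_angle

    # rigid-rod rotation toward the field axis (cortex-bound tips are held)
    if magnetic and cfg.enable_rotation:
        free = ~mt.at_cortex & (mt.L > 0)
        dpsi = _rotation_rate(mt.L, theta_B, field, consts) * dt
        mt.psi[free] = np.mod(mt.psi[free] - dpsi[free], 2.0 * np.pi)
        theta_B = mt.psi - field.direction_angle

    # tip elongation / shortening
    if magnetic and cfg.enable_rate:
        v_grow = di.v_g * _rate_factor(theta_B, field, consts)
    else:
        v_grow = np.full(n, di.v_g)
    mt.L[mt.growing] += v_grow[mt.growing] * dt
    mt.L[~mt.growing] -= di.v_s * dt

    # full depolymerization: immediate renucleation in a fresh direction
    dead = ~mt.growing & (mt.L <= 0.0)
    if np.any(dead):
        mt.L[dead] = 0.0
        mt.growing[dead] = True
        mt.at_cortex[dead] = False
        strat = mt.stratum[dead]
        fresh = np.where(
            strat >= 0,
            2.0 * np.pi * (strat + u_renuc[dead]) / mt.n_per_pole,
            u_renuc[dead] * 2.0 * np.pi,
        )
        mt.psi[dead] = np.mod(fresh, 2.0 * np.pi)

    # catastrophe / rescue (Bernoulli per step)
    cat = mt.growing & (u_event < di.f_cat * dt)
    res = ~mt.growing & (u_event < di.f_res * dt)
    mt.growing[cat] = False
    mt.growing[res] = True

    # cortex truncation and contact flag
    L_max = geom.boundary_distance(poles[mt.pole_id], mt.psi)
    np.minimum(mt.L, L_max, out=mt.L)
    mt.at_cortex = mt.L >= (L_max - cfg.contact_tol)


def _wrench_arrays(
    state: SpindleState,
    mt: _MTArrays,
    fp: ForceParams,
    field: FieldSpec,
    consts: PhysicalConstants,
    rng: np.random.Generator,
    cfg: SimConfig,
):
    """Net force (pN, 2-vector) and torque about the center (pN um)."""
    n = mt.psi.size
    u_bind = rng.random(n)
    poles = state.poles()

    ux, uy = np.cos(mt.psi), np.sin(mt.psi)
    theta_B = mt.psi - field.direction_angle
    magnetic = (field.B > 0.0)

    L_safe = np.maximum(mt.L, 1e-9)
    if magnetic and cfg.enable_bending:
        omega = _deflection_um(mt.L, theta_B, field, consts)  # signed, um
        cap = 0.99 * L_safe
        mt.clamped = np.abs(omega) > cap
        omega = np.clip(omega, -cap, cap)
        chord_factor = np.sqrt(1.0 - (omega / L_safe) ** 2)
        if cfg.bending_redirect:
            # tip displaced perpendicular to psi, toward the field axis
            dx = mt.L * ux - omega * (-uy)
            dy = mt.L * uy - omega * ux
            norm = np.hypot(dx, dy)
            norm[norm == 0] = 1.0
            cx, cy = dx / norm, dy / norm
        else:
            cx, cy = ux, uy
    else:
        mt.clamped = np.zeros(n, dtype=bool)
        chord_factor = np.ones(n)
        cx, cy = ux, uy

    # cytoplasmic length-proportional pulling along the (bent) chord
    pull = fp.alpha_cyto * mt.L * chord_factor
    fx = pull * cx
    fy = pull * cy

    # cortical interactions
    contact = mt.at_cortex
    if np.any(contact):
        fx[contact] -= fp.f_push * ux[contact]
        fy[contact] -= fp.f_push * uy[contact]
        bound = contact & (u_bind < fp.p_bind)
        fx[bound] += fp.f_dyn * chord_factor[bound] * ux[bound]
        fy[bound] += fp.f_dyn * chord_factor[bound] * uy[bound]

    force = np.array([fx.sum(), fy.sum()])
    arm = poles[mt.pole_id] - state.center
    torque = float(np.sum(arm[:, 0] * fy - arm[:, 1] * fx))

    # rigid-rod magnetic torque transmitted to the spindle body
    if magnetic and cfg.enable_rotation:
        coeff = PROTOFILAMENTS * consts.delta_chi * field.B**2 / (2.0 * consts.d0 * consts.mu0)
        tau_mag_Nm = -coeff * np.sum((mt.L * 1e-6) * np.sin(2.0 * theta_B))
        torque += tau_mag_Nm * 1e18  # N m -> pN um

    return force, torque


# ---------------------------------------------------------------------------
# public operations


def nucleate_ensemble(state: SpindleState, cfg: SimConfig, rng: np.random.Generator) -> list:
    """Nucleate ``cfg.n_mt`` zero-length growing microtubules per pole.

    Directions are uniform on [0, 2pi) (stratified by default, see module
    docstring); a fixed seed yields an identical ensemble.
    """
    arrays = _MTArrays.nucleate(cfg.n_mt, cfg.nucleation, rng)
    return arrays.to_list()


def step_microtubule(
    mt: Microtubule,
    di: DynamicInstabilityParams,
    field: FieldSpec,
    consts: PhysicalConstants,
    dt: float,
    rng: np.random.Generator,
    geom: Optional[CellGeometry] = None,
    pole_pos: Optional[np.ndarray] = None,
    cfg: Optional[SimConfig] = None,
) -> Microtubule:
    """Advance a single microtubule by one timestep (scalar convenience
    wrapper over the vectorized kernel; ``simulate`` uses the arrays
    directly).

    Growing tips elongate at the direction-dependent polymerization
    speed; shrinking tips shorten at v_s and renucleate from zero length;
    catastrophe/rescue fire as Bernoulli(f dt) events; free filaments
    rotate toward the field axis; tips beyond the cortex (if ``geom`` is
    given) are truncated to the boundary and flagged.
    """
    if dt <= 0:
        raise TimestepError("dt must be > 0")
    if max(di.f_cat, di.f_res) * dt > 1.0:
        raise TimestepError(f"event probability exceeds 1 at dt={dt}; reduce dt")
    cfg = cfg or SimConfig(dt=dt, n_mt=1)
    if geom is None:
        geom = CellGeometry(1e9, 1e9 - 1.0)  # effectively unbounded
    if pole_pos is None:
        pole_pos = np.zeros(2)
    arrays = _MTArrays.from_list([mt])
    arrays.n_per_pole = cfg.n_mt
    poles = np.stack([pole_pos, pole_pos])
    _step_arrays(arrays, poles, di, field, consts, dt, rng, geom, cfg)
    return arrays.to_list()[0]


def net_wrench(
    state: SpindleState,
    mts: Sequence[Microtubule],
    fp: ForceParams,
    field: FieldSpec,
    consts: PhysicalConstants,
    rng: np.random.Generator,
    cfg: Optional[SimConfig] = None,
):
    """Net force (pN 2-vector) and torque about the spindle center
    (pN um, scalar) exerted by an ensemble of microtubules.

    Per filament: a cytoplasmic pull of magnitude alpha_cyto * L along
    the growth direction; at the cortex a polymerization push -f_push
    along psi and, with probability p_bind, a dynein pull +f_dyn along
    psi.  With the field on, every pulling magnitude is reduced by the
    chord projection of the bent filament (optionally also redirected
    along the pole-to-deflected-tip chord), and the net rigid-rod
    magnetic torque acts on the spindle body.
    """
    if not mts:
        return np.zeros(2), 0.0
    cfg = cfg or SimConfig()
    arrays = _MTArrays.from_list(mts)
    return _wrench_arrays(state, arrays, fp, field, consts, rng, cfg)


def simulate(
    init: SpindleState,
    geom: CellGeometry = CellGeometry(),
    cfg: SimConfig = SimConfig(),
    di: DynamicInstabilityParams = DynamicInstabilityParams(),
    fp: ForceParams = ForceParams(),
    consts: PhysicalConstants = PhysicalConstants(),
) -> Trajectory:
    """Run one overdamped Monte Carlo positioning simulation.

    Each step: advance every microtubule (growth, switching, rotation,
    cortex truncation), evaluate the net wrench, then move the rigid
    spindle by force/Gamma_t*dt and torque/Gamma_r*dt.  Poles are kept
    inside the cell (1 um margin).  Bit-reproducible for a fixed seed.
    """
    init.validate_inside(geom)
    if max(di.f_cat, di.f_res) * cfg.dt > 1.0:
        raise TimestepError(f"event probability exceeds 1 at dt={cfg.dt}; reduce dt")

    rng = np.random.default_rng(cfg.seed)
    state = init.copy()
    mt = _MTArrays.nucleate(cfg.n_mt, cfg.nucleation, rng)
    if cfg.init_mt == "spanning":
        poles0 = state.poles()
        mt.L = geom.boundary_distance(poles0[mt.pole_id], mt.psi)
        mt.at_cortex = np.ones_like(mt.at_cortex)

    n_steps = int(round(cfg.t_max / cfg.dt))
    rec_t = [0.0]
    rec_d = [state.offset]
    rec_a = [state.alpha]

    for k in range(1, n_steps + 1):
        poles = state.poles()
        _step_arrays(mt, poles, di, cfg.field, consts, cfg.dt, rng, geom, cfg)
        force, torque = _wrench_arrays(state, mt, fp, cfg.field, consts, rng, cfg)

        state.center = state.center + force / fp.Gamma_t * cfg.dt
        state.alpha = state.alpha + torque / fp.Gamma_r * cfg.dt

        if state.offset > geom.a:
            raise InstabilityError(cfg.dt)
        # keep poles inside the cell with a margin
        for _ in range(64):
            if np.all(geom.contains(state.poles(), margin=1.0)):
                break
            state.center = state.center * 0.95
        else:
            raise InstabilityError(cfg.dt)

        if k % cfg.stride == 0 or k == n_steps:
            rec_t.append(k * cfg.dt)
            rec_d.append(state.offset)
            rec_a.append(state.alpha)

    return Trajectory(
        t=np.array(rec_t),
        d=np.array(rec_d),
        alpha=np.array(rec_a),
        meta={
            "seed": cfg.seed,
            "field": cfg.field.to_dict(),
            "geometry": geom.to_dict(),
            "n_mt": cfg.n_mt,
            "dt": cfg.dt,
        },
    )


def run_ensemble(
    init: SpindleState,
    geom: CellGeometry,
    cfg: SimConfig,
    di: DynamicInstabilityParams = DynamicInstabilityParams(),
    fp: ForceParams = ForceParams(),
    consts: PhysicalConstants = PhysicalConstants(),
    seeds: Optional[Sequence[int]] = None,
) -> list:
    """Run ``cfg.ensemble_n`` independent replicates (seeds cfg.seed,
    cfg.seed+1, ... unless given explicitly) from the same initial state."""
    if seeds is None:
        seeds = [cfg.seed + i for i in range(cfg.ensemble_n)]
    return [simulate(init.copy(), geom, cfg.replace(seed=int(s)), di, fp, consts) for s in seeds]


def ensemble_mean(trajectories: Sequence[Trajectory]):
    """Pointwise ensemble mean of |offset| and |orientation error|.

    The orientation error is wrapped to [-pi/2, pi/2] (a spindle aligned
    at alpha = pi is aligned with the long axis) before taking the
    absolute value.  Returns (t, mean_d, mean_abs_alpha).
    """
    t = trajectories[0].t
    for tr in trajectories[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("trajectories must share a common time grid")
    d = np.mean([tr.d for tr in trajectories], axis=0)
    wrapped = [np.abs(_wrap_half_pi(tr.alpha)) for tr in trajectories]
    a = np.mean(wrapped, axis=0)
    return t, d, a


def _wrap_half_pi(alpha: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi/2, pi/2) modulo pi (spindle axis symmetry)."""
    return (np.asarray(alpha) + np.pi / 2) % np.pi - np.pi / 2
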