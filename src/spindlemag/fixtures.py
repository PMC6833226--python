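"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here from a single
integer seed: noisy exponential decay series (ground truth for the
relaxation-time estimator), randomized initial spindle states inside an
elliptical cell, and paired field-on/field-off simulation configurations
sharing seeds for variance reduction.

Seed discipline: one global seed fans out to independent per-component
streams through ``numpy.random.SeedSequence(seed, spawn_key=(k,))``
with a fixed component index k, so adding new fixture kinds never
perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Tuple

import numpy as np

from .constants import FieldSpec
from .errors import DomainError
from .geometry import CellGeometry, SpindleState
from .simulator import SimConfig

__all__ = [
    "FixtureSpec",
    "component_rng",
    "make_decay_series",
    "make_init_condition_sweep",
    "make_paired_field_ensemble",
]

# fixed component indices of the seed-splitting rule
_STREAMS = {"decay_series": 0, "init_condition_sweep": 1, "paired_field_ensemble": 2, "simulate": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture: kind, parameters, seed.

    A fixture is fully reproducible from this triple alone.
    """

    kind: str
    parameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("decay_series", "mt_ensemble", "init_condition_sweep", "paired_field_ensemble"):
            raise DomainError(f"unknown fixture kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "parameters": dict(self.parameters), "seed": self.seed}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Per-component random stream derived from the global seed."""
    if component not in _STREAMS:
        raise DomainError(f"unknown component {component!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],)))


def make_decay_series(
    tau: float,
    y0: float = 60.0,
    noise_cv: float = 0.0,
    n_points: int = 200,
    seed: int = 0,
    t_max: float | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exponential decay y0 exp(-t/tau) with multiplicative noise.

    The noise is (1 + eps) with eps ~ Normal(0, noise_cv): i.i.d.,
    mean-zero, coefficient of variation ``noise_cv``.  Sampled on
    ``n_points`` evenly spaced times over [0, t_max] (default 5 tau).
    """
    if not (tau > 0):
        raise DomainError("tau must be > 0")
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    t = np.linspace(0.0, t_max if t_max is not None else 5.0 * tau, n_points)
    y = y0 * np.exp(-t / tau)
    if noise_cv > 0:
        rng = component_rng(seed, "decay_series")
        y = y * (1.0 + noise_cv * rng.standard_normal(n_points))
    return t, y


def make_init_condition_sweep(
    geom: CellGeometry,
    n: int,
    seed: int = 0,
    half_separation: float = 30.0,
) -> List[SpindleState]:
    """Randomized initial spindle states inside the cell.

    Centers are uniform over the concentric half-scale ellipse, angles
    uniform on [-pi/2, pi/2); states whose poles would leave the cell are
    rejected and redrawn, so every returned state is valid.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = component_rng(seed, "init_condition_sweep")
    states: List[SpindleState] = []
    while len(states) < n:
        # uniform over the half-scale ellipse via the unit-disc trick
        r = np.sqrt(rng.random())
        phi = rng.random() * 2.0 * np.pi
        center = np.array([0.5 * geom.a * r * np.cos(phi), 0.5 * geom.b * r * np.sin(phi)])
        alpha = rng.random() * np.pi - np.pi / 2
        state = SpindleState(center=center, alpha=alpha, half_separation=half_separation)
        if np.all(geom.contains(state.poles())):
            states.append(state)
    return states


def make_paired_field_ensemble(
    cfg: SimConfig,
    B_values: Tuple[float, float] = (0.0, 9.0),
) -> Tuple[List[SimConfig], List[SimConfig]]:
    """Paired field-off/field-on configurations with shared seeds.

    Returns two lists of ``cfg.ensemble_n`` configs; pair i differs only
    in the field strength (B = 0 vs 9 T by default) and shares the seed
    ``cfg.seed + i``, so field effects can be measured as paired
    differences with common random numbers.
    """
    lo, hi = B_values
    controls, exposed = [], []
    for i in range(cfg.ensemble_n):
        seed_i = cfg.seed + i
        controls.append(cfg.replace(seed=seed_i, field=FieldSpec(lo, cfg.field.direction_angle)))
        exposed.append(cfg.replace(seed=seed_i, field=FieldSpec(hi, cfg.field.direction_angle)))
    return controls, exposed
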