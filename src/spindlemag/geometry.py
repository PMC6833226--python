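"""Elliptical cell geometry and the rigid spindle state.

Lengths in this module (and throughout the simulator) are micrometres;
the default cell is the first-cleavage zebrafish blastomere, an ellipse
with long axis 600 um and short axis 300 um, with its long axis along
the lab x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

__all__ = ["CellGeometry", "SpindleState"]


@dataclass(frozen=True)
class CellGeometry:
    """Elliptical cell cross-section, semi-axes in micrometres."""

    a: float = 300.0  # semi-major, along x
    b: float = 150.0  # semi-minor, along y

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and self.a >= self.b > 0):
            raise InvalidGeometryError(f"need a >= b > 0, got a={self.a}, b={self.b}")

    def scaled(self, factor: float) -> "CellGeometry":
        return CellGeometry(self.a * factor, self.b * factor)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points (..., 2) lie inside the ellipse shrunk by
        ``margin`` (um) on each semi-axis."""
        p = np.asarray(points, dtype=float)
        a, b = self.a - margin, self.b - margin
        if a <= 0 or b <= 0:
            raise InvalidGeometryError("margin exceeds the semi-minor axis")
        return (p[..., 0] / a) ** 2 + (p[..., 1] / b) ** 2 <= 1.0

    def boundary_distance(self, origin: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Distance from interior point(s) to the cortex along direction psi.

        Solves |(x0 + t cos psi)/a|^2 + |(y0 + t sin psi)/b|^2 = 1 for the
        positive root.  ``origin`` broadcasts against ``psi``.
        """
        origin = np.asarray(origin, dtype=float)
        psi = np.asarray(psi, dtype=float)
        cx, sy = np.cos(psi), np.sin(psi)
        x0 = origin[..., 0]
        y0 = origin[..., 1]
        A = (cx / self.a) ** 2 + (sy / self.b) ** 2
        Bq = 2.0 * (x0 * cx / self.a**2 + y0 * sy / self.b**2)
        C = (x0 / self.a) ** 2 + (y0 / self.b) ** 2 - 1.0
        disc = Bq**2 - 4.0 * A * C
        disc = np.maximum(disc, 0.0)  # origin on/inside boundary
        t = (-Bq + np.sqrt(disc)) / (2.0 * A)
        return np.maximum(t, 0.0)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}


@dataclass
class SpindleState:
    """Rigid mitotic spindle: two poles a fixed distance apart.

    ``center`` is the midpoint (um), ``alpha`` the angle of the pole-pole
    axis to the cell long axis (rad), ``half_separation`` the fixed half
    pole-pole distance (um) — spindle size saturates in large blastomeres,
    so it does not scale with the cell.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha: float = 0.0
    half_separation: float = 30.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).copy()
        if self.center.shape != (2,):
            raise InvalidGeometryError("spindle center must be a 2-vector")
        if not (np.isfinite(self.half_separation) and self.half_separation > 0):
            raise InvalidGeometryError("half_separation must be > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.alpha), np.sin(self.alpha)])

    def poles(self) -> np.ndarray:
        """(2, 2) array: rows are the two pole positions, um."""
        offset = self.half_separation * self.axis
        return np.stack([self.center + offset, self.center - offset])

    def validate_inside(self, geom: CellGeometry, margin: float = 0.0) -> None:
        if not np.all(geom.contains(self.poles(), margin=margin)):
            raise InvalidGeometryError("spindle poles must lie inside the cell")

    def copy(self) -> "SpindleState":
        return SpindleState(self.center.copy(), self.alpha, self.half_separation)

    @property
    def offset(self) -> float:
        """Distance of the spindle center from the cell center, um."""
        return float(np.hypot(self.center[0], self.center[1]))
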