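"""Configuration files, trajectory CSV round-trip, and run manifests.

Config files are YAML with one section per parameter group; every field
name matches the corresponding dataclass field, unknown keys are
rejected by name.  Trajectories are CSV (comma, UTF-8, header
``t_s,d_um,alpha_rad``) written with 17 significant digits so the
read(write(x)) round trip is exact in double precision.  Manifests are
JSON and record the fully resolved configuration, seeds, package version
and sha256 checksums of every output, which is enough to reproduce a run
bitwise.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import fields
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .constants import FieldSpec, PhysicalConstants
from .errors import ConfigError, TrajectoryParseError
from .geometry import CellGeometry
from .relaxation import CleavageSchedule
from .simulator import DynamicInstabilityParams, ForceParams, SimConfig, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
    "config_hash",
]

_SECTIONS = {
    "constants": PhysicalConstants,
    "field": FieldSpec,
    "geometry": CellGeometry,
    "dynamic_instability": DynamicInstabilityParams,
    "forces": ForceParams,
    "simulation": SimConfig,
    "schedule": CleavageSchedule,
}


class RunConfig:
    """Fully resolved configuration for every stage of the pipeline."""

    def __init__(
        self,
        constants: PhysicalConstants,
        field: FieldSpec,
        geometry: CellGeometry,
        dynamic_instability: DynamicInstabilityParams,
        forces: ForceParams,
        simulation: SimConfig,
        schedule: CleavageSchedule,
    ):
        self.constants = constants
        self.field = field
        self.geometry = geometry
        self.dynamic_instability = dynamic_instability
        self.forces = forces
        # keep the field inside the simulation config coherent
        self.simulation = simulation.replace(field=field)
        self.schedule = schedule

    def to_dict(self) -> dict:
        return {
            "constants": self.constants.to_dict(),
            "field": self.field.to_dict(),
            "geometry": self.geometry.to_dict(),
            "dynamic_instability": self.dynamic_instability.to_dict(),
            "forces": self.forces.to_dict(),
            "simulation": self.simulation.to_dict(),
            "schedule": self.schedule.to_dict(),
        }


def _build_section(cls, name: str, file_vals: Mapping, override_vals: Mapping):
    known = {f.name for f in fields(cls)}
    merged: dict = {}
    for source in (file_vals, override_vals):
        for key, value in source.items():
            if key not in known:
                raise ConfigError(f"unknown key {name}.{key!r} (known: {sorted(known)})")
            merged[key] = value
    if name == "simulation" and "field" in merged and isinstance(merged["field"], Mapping):
        merged["field"] = FieldSpec(**merged["field"])
    if name == "schedule" and "first_cycle_minutes" in merged:
        merged["first_cycle_minutes"] = tuple(merged["first_cycle_minutes"])
    try:
        return cls(**merged)
    except TypeError as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path: Optional[str | Path] = None, overrides: Optional[Mapping[str, Mapping]] = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, an optional YAML file,
    and optional per-section overrides, in that precedence order
    (overrides win over the file, the file over defaults).

    Unknown sections or keys raise :class:`ConfigError` naming the
    offending key.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = dict(loaded)
    overrides = dict(overrides or {})

    for section in set(data) | set(overrides):
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section {section!r} (known: {sorted(_SECTIONS)})")

    built = {}
    for name, cls in _SECTIONS.items():
        built[name] = _build_section(cls, name, data.get(name) or {}, overrides.get(name) or {})
    return RunConfig(**built)


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as CSV with 17-significant-digit floats (exact
    double-precision round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "d_um", "alpha_rad"])
        for t, d, a in zip(traj.t, traj.d, traj.alpha):
            writer.writerow([format(t, ".17g"), format(d, ".17g"), format(a, ".17g")])
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    Malformed rows (wrong column count, unparseable or non-finite
    numbers) raise :class:`TrajectoryParseError` with the line number.
    """
    t, d, a = [], [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["t_s", "d_um", "alpha_rad"]:
            raise TrajectoryParseError(1, f"bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise TrajectoryParseError(lineno, f"expected 3 columns, got {len(row)}")
            try:
                values = [float(v) for v in row]
            except ValueError as exc:
                raise TrajectoryParseError(lineno, str(exc)) from exc
            if not all(math.isfinite(v) for v in values):
                raise TrajectoryParseError(lineno, f"non-finite value in {row!r}")
            t.append(values[0])
            d.append(values[1])
            a.append(values[2])
    return Trajectory(t=np.array(t), d=np.array(d), alpha=np.array(a), meta={"source": str(path)})


def config_hash(config: Mapping) -> str:
    """Stable short hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: Mapping, seeds, outputs) -> Path:
    """Write a JSON run manifest: resolved config, seeds, version,
    timestamp, and a checksum inventory of the produced files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": dict(config),
        "config_hash": config_hash(config),
        "seeds": list(np.asarray(seeds).tolist()) if not isinstance(seeds, list) else seeds,
        "outputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in outputs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
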