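"""Run-configuration files: schema, validation, resolution.

A run is described by a single TOML (or JSON) document with optional
sections ``[system]``, ``[moves]``, ``[sweep]`` and ``[output]``.  Unknown
keys are rejected; defaults are filled in, and the fully resolved
configuration is echoed as JSON next to the outputs so a run directory is
self-describing.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import MoveSchedule
from .model import SystemConfig

__all__ = ["RunConfig", "load_config"]

_SCHEMA_VERSION = 1


class SystemSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lattice_rows: int = 20
    lattice_cols: int = 20
    spacing: float = 1.0
    temperature: float = 295.0
    relative_permittivity: float = 80.0
    lj_epsilon: float = 1.0
    lj_sigma_dipole: float = 0.5
    dipole_length: float = 0.5
    dipole_end_charge: float = 1.0
    boundary: str = "open"
    max_sweeps: int = 5000
    convergence_window: int = 500
    convergence_tol: float = 1e-6
    hard_core_floor: float = 1e-4
    coulomb_soft_core: float = 0.3
    dipole_cutoff: Optional[float] = None   # None -> no truncation


class MovesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dx: float = 0.1
    dalpha: float = math.pi / 6.0
    dopants_mobile: bool = True


class SweepSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    concentration: float = 0.0           # %, used by `simulate`
    c_grid: list[float] = Field(default_factory=lambda: [0.0])
    q: int = 0
    q_list: list[int] = Field(default_factory=list)
    L: float = 0.1
    L_list: list[float] = Field(default_factory=list)
    n_replicates: int = 10


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    out_dir: str = "."
    bitmap_scale: int = 16
    bitmap_every: int = 0                # sweeps; 0 -> final frame only


class RunConfig(BaseModel):
    """Resolved run configuration (all defaults materialized)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = _SCHEMA_VERSION
    seed: int = 0
    system: SystemSection = Field(default_factory=SystemSection)
    moves: MovesSection = Field(default_factory=MovesSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    output: OutputSection = Field(default_factory=OutputSection)

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.moves.dx > self.system.spacing / 2:
            raise ValueError(
                f"moves.dx = {self.moves.dx} exceeds spacing/2 "
                f"= {self.system.spacing / 2}")
        if self.system.boundary not in ("open", "periodic"):
            raise ValueError(f"unknown boundary {self.system.boundary!r}")
        return self

    def to_system_config(self) -> SystemConfig:
        s = self.system
        return SystemConfig(
            lattice_rows=s.lattice_rows, lattice_cols=s.lattice_cols,
            spacing=s.spacing, temperature=s.temperature,
            relative_permittivity=s.relative_permittivity,
            lj_epsilon=s.lj_epsilon, lj_sigma_dipole=s.lj_sigma_dipole,
            dipole_length=s.dipole_length,
            dipole_end_charge=s.dipole_end_charge,
            boundary=s.boundary, dx=self.moves.dx, dalpha=self.moves.dalpha,
            max_sweeps=s.max_sweeps,
            convergence_window=s.convergence_window,
            convergence_tol=s.convergence_tol,
            hard_core_floor=s.hard_core_floor,
            coulomb_soft_core=s.coulomb_soft_core,
            dipole_cutoff=(s.dipole_cutoff if s.dipole_cutoff is not None
                           else math.inf),
            seed=self.seed)

    def to_schedule(self) -> MoveSchedule:
        return MoveSchedule(dx=self.moves.dx, dalpha=self.moves.dalpha,
                            dipole_length=self.system.dipole_length,
                            dopants_mobile=self.moves.dopants_mobile)

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def write_resolved(self, path: Path | str) -> None:
        Path(path).write_text(
            json.dumps(self.resolved_dict(), indent=2, sort_keys=True) + "\n")


def load_config(path: Path | str) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration.

    Raises FileNotFoundError, a parse error, or a pydantic ValidationError
    naming the offending key.  Loading the echoed resolved config yields an
    identical configuration.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import tomllib
        data = tomllib.loads(text)
    return RunConfig.model_validate(data)
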