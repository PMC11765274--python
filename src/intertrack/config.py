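"""Run configuration: schema, defaults, YAML round-trip.

A run is fully described by a :class:`RunConfig`: the primary particle,
the surrogate track parameters (mean event energy, radial profile, event
class mix, prechemical branching), the species and reaction tables, the
timestep schedule, the (Δx, Δt) configuration grids, the replicate
normalisation energy and the master seed.  ``load_config`` accepts YAML
(JSON is a YAML subset) and fills defaults for anything omitted, so the
minimal valid config is an empty file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .reactions import ReactionTable, default_reaction_table
from .species import SpeciesTable
from .track import (
    DEFAULT_EVENT_CLASSES,
    BranchingTable,
    ParticleSpec,
    RadialProfile,
)

#: default configuration-sweep grids for the separation/delay scan
DEFAULT_DX_GRID_NM = (0.0, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_DT_GRID_PS = (1.0, 10.0, 100.0, 1.0e4, 1.0e5, 3.0e5, 7.0e5, 1.0e6)

# 40 MeV/u carbon sits close to 30 keV/um; depth 2 um keeps LET ~constant
DEFAULT_PARTICLE = dict(name="carbon", energy=40.0, let=30.0, depth=2.0)


@dataclass
class RunConfig:
    particle: ParticleSpec
    species: SpeciesTable
    reactions: ReactionTable
    branching: BranchingTable
    radial: RadialProfile = field(default_factory=RadialProfile)
    event_classes: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_CLASSES))
    mean_event_energy: float = 16.7  # eV per primary event; 6 events / 100 eV
    spur_energy: float = 62.5  # eV per spur (cluster of ~4 events)
    schedule: dict = field(
        default_factory=lambda: {"dt_min": 0.1, "dt_max": 10.0, "growth_start": 1.0e3}
    )
    dx_grid: tuple = DEFAULT_DX_GRID_NM
    dt_grid: tuple = DEFAULT_DT_GRID_PS
    target_energy_ev: float = 2.0e6  # 2 MeV replicate normalisation
    t_end_offset: float = 1.0e6  # ps of chemistry after second arrival
    points_per_decade: int = 20
    product_jitter: float = 0.0  # nm, jitter of reaction products around midpoint
    seed: int = 0

    def schedule_kwargs(self) -> dict:
        return dict(self.schedule)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------ serialised

    def to_dict(self) -> dict:
        return {
            "particle": {
                "name": self.particle.name,
                "energy": self.particle.energy,
                "let": self.particle.let,
                "depth": self.particle.depth,
            },
            "species": self.species.to_dict(),
            "reactions": self.reactions.to_records(),
            "branching": self.branching.to_dict(),
            "radial": {
                "core_sigma": self.radial.core_sigma,
                "tail_fraction": self.radial.tail_fraction,
                "tail_scale": self.radial.tail_scale,
                "spur_sigma": self.radial.spur_sigma,
            },
            "event_classes": dict(self.event_classes),
            "mean_event_energy": self.mean_event_energy,
            "spur_energy": self.spur_energy,
            "schedule": dict(self.schedule),
            "dx_grid": list(self.dx_grid),
            "dt_grid": list(self.dt_grid),
            "target_energy_ev": self.target_energy_ev,
            "t_end_offset": self.t_end_offset,
            "points_per_decade": self.points_per_decade,
            "product_jitter": self.product_jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            particle = ParticleSpec(**{**DEFAULT_PARTICLE, **d.get("particle", {})})
        except TypeError as exc:
            raise ConfigError(f"particle: {exc}") from exc
        species = (
            SpeciesTable.from_dict(d["species"]) if "species" in d else SpeciesTable()
        )
        reactions = (
            ReactionTable.from_records(d["reactions"], species)
            if "reactions" in d
            else default_reaction_table(species)
        )
        branching = (
            BranchingTable.from_dict(d["branching"], species)
            if "branching" in d
            else BranchingTable(species=species)
        )
        radial = RadialProfile(**d.get("radial", {}))
        kwargs = {
            k: d[k]
            for k in (
                "event_classes",
                "mean_event_energy",
                "spur_energy",
                "schedule",
                "target_energy_ev",
                "t_end_offset",
                "points_per_decade",
                "product_jitter",
                "seed",
            )
            if k in d
        }
        if "dx_grid" in d:
            kwargs["dx_grid"] = tuple(float(x) for x in d["dx_grid"])
            if any(x < 0 for x in kwargs["dx_grid"]):
                raise ConfigError("dx_grid: separations must be >= 0")
        if "dt_grid" in d:
            kwargs["dt_grid"] = tuple(float(x) for x in d["dt_grid"])
            if any(x < 0 for x in kwargs["dt_grid"]):
                raise ConfigError("dt_grid: delays must be >= 0")
        return cls(particle, species, reactions, branching, radial, **kwargs)


def default_config(**overrides) -> RunConfig:
    """The default run configuration, optionally with top-level overrides."""
    cfg = RunConfig.from_dict({})
    return cfg.replace(**overrides) if overrides else cfg


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
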