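"""Parametric surrogate for the physical and prechemical stages.

A full track-structure code transports the primary ion and every
secondary electron interaction-by-interaction for ~1 fs, then dissociates
the ionised/excited water molecules and thermalises sub-excitation
electrons during the prechemical stage (1 fs–1 ps).  This module replaces
both stages with a parametric sampler that reproduces their *output*: the
1-ps inventory of radiolytic species around a straight ion path, plus the
deposited energy.

Energy is deposited in *spurs*: localised clusters of a few
ionisation/excitation events around a common energy-deposition site.
Spur centres follow a Poisson process along the beam axis (+z) with mean
count LET × depth / spur_energy, each centre offset transversely by a
two-component radial profile — a narrow nm-scale core (the dense track
column) plus a heavy exponential tail reaching the μm scale (energetic
δ-electrons).  Each spur then contains a Poisson number of primary
events (mean spur_energy / mean_event_energy), spread around the centre
with a ~1 nm Gaussian.  The clustering matters: intra-spur
recombination drives the fast early decay of the primary radicals and
the prompt build-up of the molecular products, which in turn controls
how a delayed second track interacts with an aged first track.  The
tail is what lets a small, configurable fraction of species end up
beyond 500 nm of the axis — the feature that controls how far
intertrack effects reach in Δx.

Coordinates are right-handed with the beam along +z and the origin at the
scoring-volume entrance; lengths in nm, energies in eV, time in ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .species import SpeciesTable

EV_PER_KEV = 1000.0
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class ParticleSpec:
    """Primary ion: identity, specific energy, LET and scoring depth.

    ``energy`` is in MeV per nucleon, ``let`` in keV/μm, ``depth`` in μm
    (length of the scoring volume along the beam axis).  LET is a user
    supplied input — it is not derived from the energy here.
    """

    name: str
    energy: float
    let: float
    depth: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ConfigError(f"particle.energy must be > 0, got {self.energy}")
        if self.let <= 0:
            raise ConfigError(f"particle.let must be > 0, got {self.let}")
        if self.depth <= 0:
            raise ConfigError(f"particle.depth must be > 0, got {self.depth}")

    @property
    def total_energy_ev(self) -> float:
        """Mean energy deposited in the scoring volume: LET × depth (eV)."""
        return self.let * self.depth * EV_PER_KEV


@dataclass(frozen=True)
class RadialProfile:
    """Transverse spur-centre profile (core Gaussian + exponential tail)
    and the intra-spur clustering scale."""

    core_sigma: float = 3.0  # nm, track-column width
    tail_fraction: float = 0.03
    tail_scale: float = 300.0  # nm, δ-electron reach
    spur_sigma: float = 1.0  # nm, spread of events within one spur

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ConfigError("radial.tail_fraction must be in [0, 1]")
        if self.core_sigma < 0 or self.tail_scale < 0 or self.spur_sigma < 0:
            raise ConfigError("radial scales must be >= 0")


@dataclass(frozen=True)
class PrechemChannel:
    """One dissociation channel of a primary-event class.

    ``displacement`` holds one isotropic-displacement scale (nm) per
    product; the product is shifted from the event position by a 3-D
    Gaussian vector with that per-axis scale (Maxwell-distributed
    distance), emulating thermalisation / dissociative drift.
    """

    products: tuple[str, ...]
    probability: float
    displacement: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigError(f"branching probability {self.probability} not in [0,1]")
        if len(self.displacement) != len(self.products):
            raise ConfigError(
                f"channel {self.products}: need one displacement scale per product"
            )
        if any(s < 0 for s in self.displacement):
            raise ConfigError("displacement scales must be >= 0")


#: default event-class mix: ionisations dominate at these LETs
DEFAULT_EVENT_CLASSES = {"ionization": 0.75, "excitation": 0.25}

# Literature-style placeholder branching (the actual track-structure code
# values are unpublished): every ionisation yields the OH·/H3O+/e⁻aq
# triplet; excitations dissociate to OH·+H·, to H2 + 2 OH· (via O(1D)),
# or relax radiatively with no products.
DEFAULT_BRANCHING = {
    "ionization": [
        PrechemChannel(("OH", "H3O+", "e_aq"), 1.0, (0.8, 0.8, 5.0)),
    ],
    "excitation": [
        PrechemChannel(("OH", "H"), 0.50, (0.8, 0.8)),
        PrechemChannel(("H2", "OH", "OH"), 0.15, (0.8, 0.8, 0.8)),
        PrechemChannel((), 0.35, ()),
    ],
}


class BranchingTable:
    """Per event class: dissociation channels with probabilities summing to 1."""

    def __init__(
        self,
        channels: dict[str, list[PrechemChannel]] | None = None,
        species: SpeciesTable | None = None,
    ):
        self.species = species or SpeciesTable()
        self.channels = {k: list(v) for k, v in (channels or DEFAULT_BRANCHING).items()}
        for cls_name, chans in self.channels.items():
            total = sum(c.probability for c in chans)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"branching[{cls_name}]: probabilities sum to {total}, expected 1"
                )
            for c in chans:
                for s in c.products:
                    if s not in self.species:
                        raise ConfigError(
                            f"branching[{cls_name}]: unknown species '{s}'"
                        )

    def expected_yield(self, event_classes: dict[str, float]) -> np.ndarray:
        """Expected product count per primary event, per species."""
        out = np.zeros(len(self.species))
        for cls_name, p_cls in event_classes.items():
            for ch in self.channels[cls_name]:
                for s in ch.products:
                    out[self.species.index[s]] += p_cls * ch.probability
        return out

    def to_dict(self) -> dict:
        return {
            cls_name: [
                {
                    "products": list(c.products),
                    "probability": c.probability,
                    "displacement": list(c.displacement),
                }
                for c in chans
            ]
            for cls_name, chans in self.channels.items()
        }

    @classmethod
    def from_dict(cls, d: dict, species: SpeciesTable | None = None) -> "BranchingTable":
        channels = {
            cls_name: [
                PrechemChannel(
                    tuple(c["products"]),
                    float(c["probability"]),
                    tuple(c.get("displacement", [0.0] * len(c["products"]))),
                )
                for c in chans
            ]
            for cls_name, chans in d.items()
        }
        return cls(channels, species)


@dataclass
class EventSet:
    """Primary energy-deposition events of one track."""

    kinds: np.ndarray  # event-class name per event
    pos: np.ndarray  # (n, 3) nm
    energy: np.ndarray  # (n,) eV

    def __len__(self) -> int:
        return len(self.kinds)


@dataclass
class SpeciesInventory:
    """The 1-ps species inventory of one (or more) tracks."""

    species_table: SpeciesTable
    species: np.ndarray  # (n,) int index into species_table
    pos: np.ndarray  # (n, 3) nm
    track_id: np.ndarray  # (n,) int
    energy: float  # total deposited energy, eV
    time: float = 1.0  # ps

    def __len__(self) -> int:
        return len(self.species)

    def counts(self) -> np.ndarray:
        """Per-species molecule counts."""
        return np.bincount(self.species, minlength=len(self.species_table))

    def shifted(self, offset) -> "SpeciesInventory":
        return SpeciesInventory(
            self.species_table,
            self.species,
            self.pos + np.asarray(offset, dtype=float),
            self.track_id,
            self.energy,
            self.time,
        )

    def with_track_id(self, tid: int) -> "SpeciesInventory":
        return SpeciesInventory(
            self.species_table,
            self.species,
            self.pos,
            np.full(len(self.species), tid, dtype=np.int64),
            self.energy,
            self.time,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "species": [self.species_table.labels[i] for i in self.species],
                "x_nm": self.pos[:, 0],
                "y_nm": self.pos[:, 1],
                "z_nm": self.pos[:, 2],
                "track_id": self.track_id,
            }
        )


def sample_primary_events(
    spec: ParticleSpec,
    mean_event_energy: float,
    rng: np.random.Generator,
    radial: RadialProfile | None = None,
    event_classes: dict[str, float] | None = None,
    spur_energy: float = 62.5,
) -> EventSet:
    """Sample the primary ionisation/excitation events of one track.

    Events arrive in spurs: spur centres are Poisson along +z with mean
    count LET·depth/spur_energy, and each spur holds a Poisson number of
    events (mean spur_energy/mean_event_energy) clustered within
    ``radial.spur_sigma``.  Every event carries ``mean_event_energy``
    eV, so the event count has mean LET·depth/mean_event_energy and the
    expected deposited energy is exactly LET·depth (the count is
    overdispersed relative to a plain Poisson by the clustering).
    """
    if mean_event_energy <= 0:
        raise ConfigError(f"mean_event_energy must be > 0, got {mean_event_energy}")
    if spur_energy <= 0:
        raise ConfigError(f"spur_energy must be > 0, got {spur_energy}")
    radial = radial or RadialProfile()
    event_classes = event_classes or DEFAULT_EVENT_CLASSES
    names = list(event_classes)
    probs = np.array([event_classes[k] for k in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("event class probabilities must sum to 1")

    n_spurs = rng.poisson(spec.total_energy_ev / spur_energy)
    z = rng.uniform(0.0, spec.depth * NM_PER_UM, size=n_spurs)
    # transverse spur-centre offset: Gaussian core or exponential tail
    tail = rng.random(n_spurs) < radial.tail_fraction
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_spurs)
    xy_core = rng.normal(0.0, radial.core_sigma, size=(n_spurs, 2))
    r_tail = rng.exponential(radial.tail_scale, size=n_spurs)
    centers = np.empty((n_spurs, 3))
    centers[:, 0] = np.where(tail, r_tail * np.cos(phi), xy_core[:, 0])
    centers[:, 1] = np.where(tail, r_tail * np.sin(phi), xy_core[:, 1])
    centers[:, 2] = z

    per_spur = rng.poisson(spur_energy / mean_event_energy, size=n_spurs)
    n = int(per_spur.sum())
    pos = np.repeat(centers, per_spur, axis=0)
    if radial.spur_sigma > 0:
        pos = pos + radial.spur_sigma * rng.standard_normal((n, 3))
    kinds = np.asarray(names, dtype=object)[rng.choice(len(names), size=n, p=probs)]
    energy = np.full(n, mean_event_energy)
    return EventSet(kinds, pos, energy)


def apply_prechemistry(
    events: EventSet,
    branching: BranchingTable,
    rng: np.random.Generator,
) -> SpeciesInventory:
    """Dissociate primary events into the 1-ps radiolytic inventory.

    Each event independently samples one channel of its class; each
    product is displaced isotropically from the event position with the
    channel's per-product scale.  Deposited energy is carried through
    unchanged.
    """
    table = branching.species
    out_species: list[np.ndarray] = []
    out_pos: list[np.ndarray] = []
    for cls_name, chans in branching.channels.items():
        sel = np.flatnonzero(events.kinds == cls_name)
        if len(sel) == 0:
            continue
        p = np.array([c.probability for c in chans])
        choice = rng.choice(len(chans), size=len(sel), p=p)
        for c_idx, ch in enumerate(chans):
            ev = sel[choice == c_idx]
            if len(ev) == 0 or not ch.products:
                continue
            for prod, scale in zip(ch.products, ch.displacement):
                disp = scale * rng.standard_normal((len(ev), 3))
                out_pos.append(events.pos[ev] + disp)
                out_species.append(
                    np.full(len(ev), table.index[prod], dtype=np.int64)
                )
    unknown = set(events.kinds) - set(branching.channels)
    if unknown:
        raise ConfigError(f"no branching channels for event classes {sorted(unknown)}")
    if out_species:
        species = np.concatenate(out_species)
        pos = np.concatenate(out_pos)
    else:
        species = np.empty(0, dtype=np.int64)
        pos = np.empty((0, 3))
    return SpeciesInventory(
        table,
        species,
        pos,
        np.zeros(len(species), dtype=np.int64),
        float(events.energy.sum()),
    )


def generate_track(
    spec: ParticleSpec,
    branching: BranchingTable,
    seed,
    *,
    mean_event_energy: float = 16.7,
    radial: RadialProfile | None = None,
    event_classes: dict[str, float] | None = None,
    spur_energy: float = 62.5,
) -> SpeciesInventory:
    """Full surrogate pipeline: primary events → prechemistry → 1-ps inventory.

    ``seed`` may be an int, a SeedSequence, or a Generator; results are
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    events = sample_primary_events(
        spec, mean_event_energy, rng, radial, event_classes, spur_energy
    )
    return apply_prechemistry(events, branching, rng)
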