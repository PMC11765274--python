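"""Tracked radiolytic species and their transport parameters.

The chemistry tracks the seven standard products of water radiolysis:
the hydroxyl radical OH·, the hydrated electron e⁻aq, the hydronium ion
H3O⁺, the hydrogen atom H·, molecular hydrogen H2, hydrogen peroxide
H2O2 and the hydroxide ion OH⁻.  Water itself is the implicit solvent:
it is never tracked as a particle, but reactions may emit or consume it
(the emission count is recorded in the reaction log so that elemental
and charge balances close exactly).

Units follow the package-wide convention: lengths in nm, times in ps,
so diffusion coefficients are nm²/ps (1e-9 m²/s == 1e-3 nm²/ps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

#: canonical label order used for all per-species arrays
SPECIES_LABELS = ("OH", "e_aq", "H3O+", "H", "H2", "H2O2", "OH-")

#: atomic composition (n_H, n_O) and net charge of each tracked species
COMPOSITION = {
    "OH": (1, 1, 0),
    "e_aq": (0, 0, -1),
    "H3O+": (3, 1, +1),
    "H": (1, 0, 0),
    "H2": (2, 0, 0),
    "H2O2": (2, 2, 0),
    "OH-": (1, 1, -1),
}

#: implicit solvent composition, used when balancing reaction channels
WATER = (2, 1, 0)

# Self-diffusion coefficients at room temperature, nm²/ps, from the
# standard radiation-chemistry compilations (Buxton-style tables as used
# by track-structure chemistry codes).  These are configuration values,
# not fitted quantities.
DEFAULT_DIFFUSION = {
    "OH": 2.8e-3,
    "e_aq": 4.9e-3,
    "H3O+": 9.46e-3,
    "H": 7.0e-3,
    "H2": 4.8e-3,
    "H2O2": 2.3e-3,
    "OH-": 5.3e-3,
}


@dataclass(frozen=True)
class SpeciesParams:
    """One tracked species: label and diffusion coefficient D (nm²/ps)."""

    label: str
    d: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ConfigError(f"species[{self.label}].d: D must be >= 0, got {self.d}")
        if self.label not in COMPOSITION:
            raise ConfigError(f"species[{self.label}]: unknown species label")


class SpeciesTable:
    """Ordered collection of species with index lookup and array views."""

    def __init__(self, params: list[SpeciesParams] | None = None):
        if params is None:
            params = [SpeciesParams(s, DEFAULT_DIFFUSION[s]) for s in SPECIES_LABELS]
        labels = [p.label for p in params]
        if len(set(labels)) != len(labels):
            raise ConfigError("species: duplicate labels")
        self.params = tuple(params)
        self.labels = tuple(labels)
        self.index = {s: i for i, s in enumerate(labels)}
        self.d = np.array([p.d for p in params])
        comp = np.array([COMPOSITION[s] for s in labels])
        self.n_h = comp[:, 0]
        self.n_o = comp[:, 1]
        self.charge = comp[:, 2]

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def to_dict(self) -> dict:
        return {p.label: p.d for p in self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesTable":
        return cls([SpeciesParams(label, float(dc)) for label, dc in d.items()])


def composition_totals(table: SpeciesTable, counts: np.ndarray) -> tuple[int, int, int]:
    """Total (H, O, charge) carried by ``counts`` molecules of each species."""
    counts = np.asarray(counts)
    return (
        int(counts @ table.n_h),
        int(counts @ table.n_o),
        int(counts @ table.charge),
    )
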