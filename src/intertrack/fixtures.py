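"""Deterministic miniature inventories for tests and demonstrations."""

from __future__ import annotations

import numpy as np

from .errors import ConfigError
from .species import SpeciesTable
from .track import SpeciesInventory


def make_fixture(kind: str, seed: int = 0, *, species_table: SpeciesTable | None = None,
                 r0: float = 1.0, n: int = 50, spacing: float = 2.0,
                 pair=("e_aq", "H3O+")) -> SpeciesInventory:
    """Build a tiny named inventory.

    kinds:
      - ``isolated_pair``: two molecules (default e⁻aq + H3O⁺) at distance r0 nm
      - ``two_oh``: two OH· at distance r0 (forced H2O2 formation probe)
      - ``mini_track``: ~n molecules on a line with the given spacing, species
        cycled through the radiolytic set with a seeded shuffle
    """
    table = species_table or SpeciesTable()
    rng = np.random.default_rng(seed)
    if kind == "isolated_pair":
        species = np.array([table.index[pair[0]], table.index[pair[1]]])
        pos = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    elif kind == "two_oh":
        species = np.array([table.index["OH"], table.index["OH"]])
        pos = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    elif kind == "mini_track":
        primary = [table.index[s] for s in ("OH", "H3O+", "e_aq")]
        species = np.array([primary[i % 3] for i in range(n)])
        rng.shuffle(species)
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * spacing
        pos[:, :2] = rng.normal(0.0, 1.0, size=(n, 2))
    else:
        raise ConfigError(f"unknown fixture kind '{kind}'")
    return SpeciesInventory(
        table, species, pos, np.zeros(len(species), dtype=np.int64),
        energy=62.5 * max(1, len(species) // 3),
    )
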