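"""Bimolecular reaction channels and Smoluchowski reaction radii.

Each channel is defined by an unordered reactant pair, a product multiset
(0–3 tracked species; implicit water balances the rest) and a bulk rate
constant k in M⁻¹s⁻¹.  The reaction–diffusion engine treats every channel
as fully diffusion-controlled with an effective encounter radius

    R = k' / (4 π (D_a + D_b)),    k' = k · 1.6606e-12 nm³/ps,

i.e. the radius at which the stationary Smoluchowski flux reproduces the
measured rate constant.  Partially diffusion-controlled kinetics are
folded into R rather than modelled with an acceptance probability; this
is the simplest reproducible closure for a step-by-step scheme.

The default channel set is closed over the seven tracked species: the
hydronium–electron recombination, the three H·-consuming channels, the
peroxide–electron channel, plus the standard radical–radical channels
(OH·+OH·, e⁻aq+OH·, e⁻aq+e⁻aq, H·+H·) and the neutralisation
H3O⁺+OH⁻.  Rate constants are a literature compilation (they are not
printed in any single primary source used here) and live in the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .species import WATER, SpeciesTable

#: 1 M⁻¹s⁻¹ expressed in nm³/ps per molecule pair (1e24 nm³/dm³ / N_A / 1e12 ps/s)
M_INV_S_TO_NM3_PER_PS = 1.6606e-12


def smoluchowski_radius(k: float, da: float, db: float) -> float:
    """Effective encounter radius (nm) for rate constant ``k`` (M⁻¹s⁻¹).

    ``da``/``db`` are the reactant diffusion coefficients in nm²/ps.
    """
    if k < 0:
        raise ConfigError(f"rate constant must be >= 0, got {k}")
    if k == 0:
        return 0.0
    dsum = da + db
    if dsum <= 0:
        raise ConfigError("Da + Db must be > 0 for a channel with k > 0")
    return k * M_INV_S_TO_NM3_PER_PS / (4.0 * np.pi * dsum)


@dataclass(frozen=True)
class ReactionChannel:
    """One bimolecular channel ``A + B -> products (+ n H2O)``.

    ``n_h2o`` is the implicit-water emission count needed to balance the
    channel; it is negative when the channel consumes solvent (e.g.
    e⁻aq + H· → H2 + OH⁻ proceeds via a water molecule).
    """

    reactants: tuple[str, str]
    products: tuple[str, ...]
    k: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.reactants) != 2:
            raise ConfigError(f"channel {self.label()}: need exactly two reactants")
        if len(self.products) > 3:
            raise ConfigError(f"channel {self.label()}: at most 3 products")
        if self.k < 0:
            raise ConfigError(f"channel {self.label()}: k must be >= 0")
        if self.weight <= 0:
            raise ConfigError(f"channel {self.label()}: weight must be > 0")

    def label(self) -> str:
        lhs = " + ".join(self.reactants)
        rhs = " + ".join(self.products) if self.products else "H2O"
        return f"{lhs} -> {rhs}"

    def balance(self, table: SpeciesTable) -> int:
        """Return the implicit H2O count; raise ConfigError if unbalanced."""
        for s in (*self.reactants, *self.products):
            if s not in table:
                raise ConfigError(f"channel '{self.label()}': unknown species '{s}'")
        idx = table.index
        h = sum(table.n_h[idx[s]] for s in self.reactants) - sum(
            table.n_h[idx[s]] for s in self.products
        )
        o = sum(table.n_o[idx[s]] for s in self.reactants) - sum(
            table.n_o[idx[s]] for s in self.products
        )
        q = sum(table.charge[idx[s]] for s in self.reactants) - sum(
            table.charge[idx[s]] for s in self.products
        )
        n_h2o = o  # each implicit water carries one O
        if h != n_h2o * WATER[0] or q != 0:
            raise ConfigError(
                f"channel '{self.label()}' does not conserve H/charge "
                f"(excess H={h}, O={o}, q={q})"
            )
        return n_h2o


# (reactants, products, k in M⁻¹s⁻¹) — literature-compilation rate set, closed
# over the tracked species.  The OH·+H2O2 channel is omitted so that no HO2·
# needs tracking.
DEFAULT_CHANNELS: tuple[tuple[tuple[str, str], tuple[str, ...], float], ...] = (
    (("H3O+", "e_aq"), ("H",), 2.11e10),
    (("e_aq", "OH"), ("OH-",), 2.95e10),
    (("e_aq", "e_aq"), ("H2", "OH-", "OH-"), 6.36e9),
    (("e_aq", "H"), ("H2", "OH-"), 2.50e10),
    (("e_aq", "H2O2"), ("OH", "OH-"), 1.10e10),
    (("OH", "OH"), ("H2O2",), 5.50e9),
    (("OH", "H"), (), 1.55e10),
    (("H", "H"), ("H2",), 5.03e9),
    (("H3O+", "OH-"), (), 1.13e11),
)


class ReactionTable:
    """Validated channel set with per-pair radii and fast lookup matrices."""

    def __init__(self, channels: list[ReactionChannel], species: SpeciesTable):
        self.species = species
        self.channels = tuple(channels)
        self.n_h2o = tuple(ch.balance(species) for ch in channels)

        n = len(species)
        self.radius = np.array(
            [
                smoluchowski_radius(
                    ch.k,
                    species.d[species.index[ch.reactants[0]]],
                    species.d[species.index[ch.reactants[1]]],
                )
                for ch in channels
            ]
        )
        # per species-pair channel lists
        pair_channels: dict[tuple[int, int], list[int]] = {}
        for c, ch in enumerate(channels):
            a, b = sorted(species.index[s] for s in ch.reactants)
            pair_channels.setdefault((a, b), []).append(c)

        self.channel_of_pair = np.full((n, n), -1, dtype=np.int64)
        self.radius_sq = np.zeros((n, n))
        self._multi: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for (a, b), idxs in pair_channels.items():
            if len(idxs) == 1:
                self.channel_of_pair[a, b] = self.channel_of_pair[b, a] = idxs[0]
            else:
                weights = np.array([channels[c].weight for c in idxs])
                explicit = [channels[c].weight != 1.0 for c in idxs]
                if not any(explicit):
                    pair = f"{species.labels[a]} + {species.labels[b]}"
                    raise ConfigError(
                        f"pair '{pair}' has {len(idxs)} channels but no branching "
                        "weights; set 'weight' on each channel"
                    )
                self.channel_of_pair[a, b] = self.channel_of_pair[b, a] = -2
                self._multi[(a, b)] = (np.array(idxs), weights / weights.sum())
            rmax = max(self.radius[c] for c in idxs)
            self.radius_sq[a, b] = self.radius_sq[b, a] = rmax * rmax

        self.max_radius = float(self.radius.max()) if len(channels) else 0.0
        self.reactive = np.zeros(n, dtype=bool)
        for ch in channels:
            if ch.k > 0:
                for s in ch.reactants:
                    self.reactive[species.index[s]] = True

        # integer product lists per channel, for the engine
        self.product_idx = tuple(
            np.array([species.index[s] for s in ch.products], dtype=np.int64)
            for ch in channels
        )

    def pick_channel(self, a: int, b: int, rng: np.random.Generator) -> int:
        """Channel index for a reacting (species a, species b) encounter."""
        c = self.channel_of_pair[a, b]
        if c >= 0:
            return int(c)
        idxs, p = self._multi[tuple(sorted((a, b)))]
        return int(rng.choice(idxs, p=p))

    def to_records(self) -> list[dict]:
        return [
            {
                "reactants": list(ch.reactants),
                "products": list(ch.products),
                "k": ch.k,
                "weight": ch.weight,
            }
            for ch in self.channels
        ]

    @classmethod
    def from_records(cls, records: list[dict], species: SpeciesTable) -> "ReactionTable":
        channels = [
            ReactionChannel(
                tuple(r["reactants"]),
                tuple(r.get("products", ())),
                float(r["k"]),
                float(r.get("weight", 1.0)),
            )
            for r in records
        ]
        return cls(channels, species)


def default_reaction_table(species: SpeciesTable | None = None) -> ReactionTable:
    species = species or SpeciesTable()
    channels = [ReactionChannel(r, p, k) for r, p, k in DEFAULT_CHANNELS]
    return ReactionTable(channels, species)
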