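"""Radiolytic yield analysis: G-values, ΔG(μs) grids, radial statistics.

The G-value of a species is the number of molecules present (produced or
surviving) per 100 eV of energy deposited in the scoring volume,

    G(t) = N(t) / E(t) × 100,

where E(t) is a step function: only the first track's energy counts
before the delayed track arrives.  The intertrack effect of a (Δx, Δt)
configuration is summarised by the normalised yield difference one
microsecond after the second track,

    ΔG_μs = (G_pair(1 μs + Δt) − G_NI) / G_NI,

with the non-interacting (NI) reference G_NI = (G_NI(1 μs + Δt)
+ G_NI(1 μs)) / 2, the average of the two independent tracks' ages.
Negative ΔG means net depletion relative to independent tracks (typical
for the primary radicals OH·, e⁻aq, H3O⁺ at close separations), positive
means enhancement (typical for molecular products H2, H2O2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass
class GSeries:
    """Per-species time series of counts, deposited energy and yields."""

    times: np.ndarray  # (T,) ps, sorted
    species: tuple[str, ...]
    counts: np.ndarray  # (T, S) N(t)
    energy: np.ndarray  # (T,) eV, non-decreasing step function
    track_counts: np.ndarray | None = None  # (T, S, K) per-parent-track N(t)

    def g(self) -> np.ndarray:
        """(T, S) array of G-values, molecules per 100 eV."""
        return self.counts / self.energy[:, None] * 100.0

    def index_at(self, t: float) -> int:
        """Index of the latest logged time <= t (no interpolation)."""
        i = int(np.searchsorted(self.times, t * (1 + 1e-12), side="right")) - 1
        if i < 0:
            raise ConfigError(f"no logged time at or before t={t}")
        return i

    def g_at(self, t: float) -> np.ndarray:
        """(S,) G-values at the nearest logged time <= t."""
        return self.g()[self.index_at(t)]

    def n_at(self, t: float) -> np.ndarray:
        return self.counts[self.index_at(t)]

    def to_frame(self) -> pd.DataFrame:
        g = self.g()
        rows = []
        for si, s in enumerate(self.species):
            rows.append(
                pd.DataFrame(
                    {
                        "time_ps": self.times,
                        "species": s,
                        "N": self.counts[:, si],
                        "E_eV": self.energy,
                        "G": g[:, si],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def gvalue(n: float, e: float) -> float:
    """G-value: molecules per 100 eV of deposited energy."""
    if e <= 0:
        raise ConfigError(f"deposited energy must be > 0, got {e}")
    return n / e * 100.0


def peak_drop_expectation(n1_at_dt: float, n2_at_1ps: float, e1: float, e2: float) -> float:
    """G-value at the instant the delayed track activates.

    A counting identity: the first track contributes its (aged) N at Δt,
    the second its fresh 1-ps inventory, and the energies add.  Primary
    species show a peak (their fresh yield exceeds the aged one),
    secondary species a drop (the fresh track carries none).
    """
    return gvalue(n1_at_dt + n2_at_1ps, e1 + e2)


def delta_g_mus(g_pair: float, g_ni_ref: float) -> float:
    """Normalised intertrack yield change at 1 μs after the second track."""
    if g_ni_ref <= 0:
        raise ConfigError("NI reference G-value must be > 0")
    return (g_pair - g_ni_ref) / g_ni_ref


def ni_reference(series: GSeries, dt_ps: float, t_chem: float = 1.0e6) -> np.ndarray:
    """(S,) NI reference yields: mean of G_NI(1 μs + Δt) and G_NI(1 μs)."""
    return 0.5 * (series.g_at(t_chem + dt_ps) + series.g_at(t_chem))


def transverse_radii(pos: np.ndarray, axis_xy=(0.0, 0.0)) -> np.ndarray:
    """Distance of each molecule from its track axis (beam along +z)."""
    pos = np.asarray(pos, dtype=float)
    dx = pos[:, 0] - axis_xy[0]
    dy = pos[:, 1] - axis_xy[1]
    return np.hypot(dx, dy)


def r80(radii: np.ndarray) -> float:
    """Smallest radius containing at least 80% of the molecules."""
    radii = np.sort(np.asarray(radii, dtype=float))
    n = len(radii)
    if n == 0:
        raise ConfigError("r80 of an empty set is undefined")
    k = math.ceil(0.8 * n)
    return float(radii[k - 1])


def fraction_beyond(radii: np.ndarray, radius: float = 500.0) -> float:
    """Percentage of molecules farther than ``radius`` nm from the axis."""
    radii = np.asarray(radii, dtype=float)
    if len(radii) == 0:
        raise ConfigError("fraction of an empty set is undefined")
    return float((radii > radius).mean() * 100.0)


def significance(pair_g: np.ndarray, ni_g: np.ndarray) -> float:
    """Two-sample Student t-test p-value, pair-run vs NI replicate yields.

    Degenerate zero-variance inputs are resolved by the limit: identical
    means give p = 1, different means p = 0.
    """
    pair_g = np.asarray(pair_g, dtype=float)
    ni_g = np.asarray(ni_g, dtype=float)
    if pair_g.std() == 0.0 and ni_g.std() == 0.0:
        return 1.0 if pair_g.mean() == ni_g.mean() else 0.0
    t = stats.ttest_ind(pair_g, ni_g, equal_var=True)
    return float(t.pvalue)


@dataclass
class DeltaGGrid:
    """ΔG_μs over the (Δx, Δt) configuration grid, one row per cell/species."""

    table: pd.DataFrame  # columns: species, dx_nm, dt_ps, delta_g, se, n, p

    def pivot(self, species: str, value: str = "delta_g") -> pd.DataFrame:
        sub = self.table[self.table.species == species]
        return sub.pivot(index="dt_ps", columns="dx_nm", values=value)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cell_statistics(
    pair_g: np.ndarray, ni_g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-species (ΔG, SE(ΔG), p) from replicate end-point yields.

    ``pair_g``/``ni_g`` have shape (n_replicates, S).  ΔG uses the ratio
    of replicate means; its standard error combines both samples by the
    delta method.  Species absent from the NI reference give NaN.
    """
    pair_g = np.atleast_2d(np.asarray(pair_g, dtype=float))
    ni_g = np.atleast_2d(np.asarray(ni_g, dtype=float))
    mp, mn = pair_g.mean(axis=0), ni_g.mean(axis=0)
    sp = pair_g.std(axis=0, ddof=1) / np.sqrt(pair_g.shape[0])
    sn = ni_g.std(axis=0, ddof=1) / np.sqrt(ni_g.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(mn > 0, (mp - mn) / mn, np.nan)
        se = np.where(mn > 0, np.sqrt(sp**2 + (mp / mn) ** 2 * sn**2) / mn, np.nan)
    p = np.array(
        [significance(pair_g[:, s], ni_g[:, s]) for s in range(pair_g.shape[1])]
    )
    return delta, se, p


def build_grid(
    species: tuple[str, ...],
    pair_end_g: dict[tuple[float, float], np.ndarray],
    ni_ref_g: dict[float, np.ndarray],
) -> DeltaGGrid:
    """Assemble the ΔG_μs grid from per-cell replicate yields.

    ``pair_end_g[(dx, dt)]`` holds the (n, S) pair-run yields at
    1 μs + Δt; ``ni_ref_g[dt]`` the (n, S) NI reference yields (shared
    across Δx at the same delay).
    """
    rows = []
    for (dx, dt), pg in sorted(pair_end_g.items()):
        ng = ni_ref_g[dt]
        delta, se, p = cell_statistics(pg, ng)
        for si, s in enumerate(species):
            rows.append(
                {
                    "species": s,
                    "dx_nm": dx,
                    "dt_ps": dt,
                    "delta_g": delta[si],
                    "se": se[si],
                    "n": np.atleast_2d(pg).shape[0],
                    "p": p[si],
                }
            )
    return DeltaGGrid(pd.DataFrame(rows))


def holm_significant(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down test: which hypotheses are rejected at FWER ``alpha``.

    Used when a *family* of per-species tests must answer a single
    question ("does any species differ from NI at this separation?");
    the raw per-species p-values are still reported alongside.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def no_effect_boundary(
    grid: DeltaGGrid, dx_scan, alpha: float = 0.05
) -> float | None:
    """Smallest scanned Δx at and beyond which no species is significant.

    Significance within each Δx is assessed as a family over species
    (Holm-corrected at FWER ``alpha``), since the question is whether
    *any* species still differs from the NI scenario.  Returns None when
    even the largest scanned separation shows an effect.
    """
    dx_scan = sorted(float(d) for d in dx_scan)
    effect = {}
    for dx in dx_scan:
        sub = grid.table[np.isclose(grid.table.dx_nm, dx)]
        pv = sub.groupby("dt_ps")["p"].apply(list)
        effect[dx] = any(holm_significant(np.array(p), alpha).any() for p in pv)
    for i, dx in enumerate(dx_scan):
        if not any(effect[d] for d in dx_scan[i:]):
            return dx
    return None
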