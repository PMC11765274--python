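"""Standard evaluation protocols: pair-vs-NI cells and boundary scans.

These wrap the replicate orchestration used by both the benchmark script
and the heavier end-to-end tests: one (Δx, Δt) cell is 'n' interacting
pair runs plus 'n' non-interacting reference runs (the NI sample is
shared across Δx at the same delay), reduced to per-replicate end-point
yields and the ΔG_μs cell statistics.
"""

from __future__ import annotations

import numpy as np

from . import multitrack as mt
from .analysis import build_grid
from .config import RunConfig


def ni_sample(cfg: RunConfig, dt_ps: float, n: int, seed) -> np.ndarray:
    """(n, S) NI reference yields at one delay."""
    runs = mt.run_ni_replicates(cfg, dt_ps, n, seed)
    return mt.ni_reference_yields(runs, dt_ps, cfg.t_end_offset)


def pair_sample(cfg: RunConfig, dx_nm: float, dt_ps: float, n: int, seed) -> np.ndarray:
    """(n, S) pair-run yields at 1 μs after the second arrival."""
    runs = mt.run_pair_replicates(cfg, dx_nm, dt_ps, n, seed)
    return mt.end_point_yields(runs, dt_ps, cfg.t_end_offset)


def evaluate_cells(
    cfg: RunConfig,
    dx_values,
    dt_ps: float,
    n: int,
    seed,
    *,
    ni: np.ndarray | None = None,
):
    """Evaluate several Δx at one Δt against a shared NI sample.

    Returns ``(grid, ni)`` where ``grid`` is the assembled
    :class:`~intertrack.analysis.DeltaGGrid` restricted to these cells.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if ni is None:
        ni = ni_sample(cfg, dt_ps, n, root.spawn(1)[0])
    pair_end = {}
    for dx in dx_values:
        pair_end[(float(dx), float(dt_ps))] = pair_sample(cfg, dx, dt_ps, n, root.spawn(1)[0])
    grid = build_grid(cfg.species.labels, pair_end, {float(dt_ps): ni})
    return grid, ni


def max_abs_delta_g(grid) -> float:
    """Largest |ΔG_μs| over species in a grid, as a percentage."""
    return float(np.nanmax(np.abs(grid.table.delta_g.to_numpy())) * 100.0)


def paired_delta_g(cfg: RunConfig, dx_nm: float, dt_ps: float, n: int, seed):
    """Per-replicate ΔG_μs with seed-matched pair and NI runs.

    Reusing one seed for both arms gives both runs identical 1-ps
    inventories, so the initial-yield fluctuations cancel in the
    per-replicate difference — a large variance reduction for species
    with small absolute counts (H2, H2O2).  Returns an (n, S) array of
    per-replicate ΔG values (NaN where the NI yield is zero).
    """
    from .analysis import ni_reference

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n):
        pr = mt.run_pair(cfg, dx_nm, dt_ps, child)
        ni = mt.run_ni(cfg, dt_ps, child)
        gp = pr.series.g_at(max(dt_ps, 1.0) + cfg.t_end_offset)
        gn = ni_reference(ni.series, dt_ps, cfg.t_end_offset)
        with np.errstate(divide="ignore", invalid="ignore"):
            out.append(np.where(gn > 0, (gp - gn) / gn, np.nan))
    return np.array(out)
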