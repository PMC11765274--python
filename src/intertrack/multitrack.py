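"""Two-track orchestration: spatial offset Δx, temporal delay Δt.

A pair run places track 1 at (+Δx/2, 0, 0) and track 2 at (−Δx/2, 0, 0),
both along +z.  Track 2's 1-ps inventory is sampled immediately (its
physical and prechemical stages are independent of track 1) but kept
*frozen* — invisible to diffusion, reactions and N(t) — until the global
clock reaches Δt.  At activation the molecules unfreeze, the deposited
energy steps up by E2, and the timestep schedule resets to its minimum
to resolve the fresh track's fast kinetics.  Evolution continues to 1 μs
after the second arrival.

The non-interacting (NI) reference evolves the same two tracks with
cross-track reactions disabled, to 1 μs + Δt; the scalar NI reference
yield averages the two track ages (see :mod:`intertrack.analysis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import GSeries, ni_reference
from .engine import ChemistryEngine, SimulationState, TimestepSchedule, state_from_inventories
from .errors import ConfigError
from .track import ParticleSpec, generate_track

T_CHEM_START = 1.0  # ps — chemical stage begins at the 1-ps inventory


@dataclass(frozen=True)
class MultiTrackConfig:
    """One intertrack configuration: particle, Δx (nm), Δt (ps), replicates."""

    particle: ParticleSpec
    dx_nm: float = 0.0
    dt_ps: float = 1.0
    replicates: int = 1
    seed: int = 0
    t_end_offset: float = 1.0e6  # ps of chemistry after the second arrival

    def __post_init__(self) -> None:
        if self.dx_nm < 0 or self.dt_ps < 0:
            raise ConfigError("dx_nm and dt_ps must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass
class PairRunResult:
    """Everything a pair run produces, per replicate."""

    series: GSeries
    e1: float
    e2: float
    n1_1ps: np.ndarray  # per-species 1-ps counts of track 1
    n2_1ps: np.ndarray  # per-species 1-ps counts of track 2 (frozen inventory)
    t_activation: float  # ps (clamped to >= 1 ps)
    state: SimulationState | None = None

    def g_at_activation(self) -> np.ndarray:
        return self.series.g_at(self.t_activation)

    def n1_at_activation(self) -> np.ndarray:
        idx = self.series.index_at(self.t_activation)
        return self.series.track_counts[idx, :, 0]


def log_grid(t_start: float, t_end: float, points_per_decade: int = 20, forced=()) -> np.ndarray:
    """Log-spaced logging times with forced exact points."""
    n = max(2, int(math.ceil(math.log10(t_end / t_start) * points_per_decade)) + 1)
    times = np.geomspace(t_start, t_end, n)
    times = np.union1d(times, np.asarray(list(forced), dtype=float))
    return times[(times >= t_start - 1e-9) & (times <= t_end + 1e-9)]


def _build_engine(run_cfg, intertrack: bool) -> ChemistryEngine:
    return ChemistryEngine(
        run_cfg.species,
        run_cfg.reactions,
        TimestepSchedule(**run_cfg.schedule_kwargs()),
        intertrack=intertrack,
        product_jitter=run_cfg.product_jitter,
    )


def run_pair(run_cfg, dx_nm: float, dt_ps: float, seed, *, intertrack: bool = True,
             keep_state: bool = False, t_end: float | None = None,
             extra_log=()) -> PairRunResult:
    """Simulate one track pair through the chemical stage.

    ``run_cfg`` is a :class:`intertrack.config.RunConfig`; ``seed`` may be
    an int or a SeedSequence.  With ``intertrack=False`` the same
    machinery runs but cross-track reactions are suppressed (the NI
    scenario at the same geometry).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_t1, s_t2, s_chem = ss.spawn(3)
    spec = run_cfg.particle
    track_kwargs = dict(
        mean_event_energy=run_cfg.mean_event_energy,
        radial=run_cfg.radial,
        event_classes=run_cfg.event_classes,
        spur_energy=run_cfg.spur_energy,
    )
    inv1 = generate_track(spec, run_cfg.branching, s_t1, **track_kwargs
                          ).shifted((+dx_nm / 2.0, 0.0, 0.0)).with_track_id(0)
    inv2 = generate_track(spec, run_cfg.branching, s_t2, **track_kwargs
                          ).shifted((-dx_nm / 2.0, 0.0, 0.0)).with_track_id(1)

    t_act = max(dt_ps, T_CHEM_START)  # activation never precedes the 1-ps start
    active_from_start = t_act <= T_CHEM_START
    state = state_from_inventories([inv1, inv2], [True, active_from_start], T_CHEM_START)
    engine = _build_engine(run_cfg, intertrack)
    engine.schedule.reset(T_CHEM_START)

    if t_end is None:
        t_end = t_act + run_cfg.t_end_offset
    forced = {T_CHEM_START, t_act, t_end}
    forced.update(float(t) for t in extra_log if T_CHEM_START <= t <= t_end)
    times = log_grid(T_CHEM_START, t_end, run_cfg.points_per_decade, forced)

    events = []
    if not active_from_start:
        def activate(st: SimulationState, eng: ChemistryEngine) -> None:
            eng._invalidate(st)  # flush positions before the active set changes
            st.activate_track(1)
            st.add_energy(inv2.energy)
            eng.schedule.reset(st.time)

        events.append((t_act, activate))

    rng = np.random.default_rng(s_chem)
    series = engine.evolve(state, t_end, times, rng, events)
    return PairRunResult(
        series=series,
        e1=inv1.energy,
        e2=inv2.energy,
        n1_1ps=inv1.counts(),
        n2_1ps=inv2.counts(),
        t_activation=t_act,
        state=state if keep_state else None,
    )


def run_ni(run_cfg, dt_ps: float, seed, *, keep_state: bool = False) -> PairRunResult:
    """Non-interacting reference: both tracks active from 1 ps, no cross
    reactions, evolved to 1 μs + Δt.

    The returned series is the independent-track aggregate G_NI(t); the
    scalar reference for ΔG_μs is :func:`intertrack.analysis.ni_reference`.
    """
    t_chem = run_cfg.t_end_offset
    # both tracks start together; the delay enters only through the end time
    return run_pair(
        run_cfg, dx_nm=0.0, dt_ps=0.0, seed=seed, intertrack=False,
        keep_state=keep_state, t_end=t_chem + dt_ps,
        extra_log=(t_chem, t_chem + dt_ps),
    )


def replicate_count(target_energy_ev: float, spec: ParticleSpec) -> int:
    """Replicates needed to deposit ``target_energy_ev`` in total.

    The number of independent simulations × LET × depth normalises every
    configuration to the same total energy (default 2 MeV).
    """
    if target_energy_ev <= 0:
        raise ConfigError("target energy must be > 0")
    return int(math.ceil(target_energy_ev / spec.total_energy_ev))


def run_pair_replicates(run_cfg, dx_nm, dt_ps, n, seed, *, intertrack=True):
    """n independent pair runs with child seed streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        run_pair(run_cfg, dx_nm, dt_ps, child, intertrack=intertrack)
        for child in ss.spawn(n)
    ]


def run_ni_replicates(run_cfg, dt_ps, n, seed):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [run_ni(run_cfg, dt_ps, child) for child in ss.spawn(n)]


def end_point_yields(results: list[PairRunResult], dt_ps: float, t_chem: float = 1.0e6) -> np.ndarray:
    """(n, S) pair-run yields at 1 μs after the second arrival."""
    return np.stack([r.series.g_at(max(dt_ps, T_CHEM_START) + t_chem) for r in results])


def ni_reference_yields(results: list[PairRunResult], dt_ps: float, t_chem: float = 1.0e6) -> np.ndarray:
    """(n, S) NI reference yields (age-averaged footnote formula)."""
    return np.stack([ni_reference(r.series, dt_ps, t_chem) for r in results])
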