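"""Step-by-step heterogeneous chemical stage.

From 1 ps to ~1 μs every active molecule performs Brownian diffusion
(independent Gaussian increments, per-axis std sqrt(2 D dt)) and reacts
with any partner found inside the channel's Smoluchowski radius.  The
timestep grows adaptively from 0.1 ps, when intra-spur kinetics are fast,
to 10 ps once the track has relaxed; a delayed second track resets the
schedule when it activates so its fast early kinetics are resolved too.

Pair detection uses a cKD-tree with a Verlet (skin) candidate list: the
tree is rebuilt only when the accumulated maximum single-molecule
displacement exceeds half the skin, which guarantees that no pair can
enter the reaction radius undetected between rebuilds.  A pair reacts
when its end-of-step separation falls inside the channel radius R, or —
to keep the capture rate timestep-independent once dt has grown — with
the Brownian-bridge crossing probability

    P = exp(−(d0 − R)(d1 − R) / (D_rel dt)),   d0, d1 > R,

the chance that the pair's separation crossed R at some instant during
a step that started at distance d0 and ended at d1.  Candidate pairs
are processed in increasing-distance order and each molecule reacts at
most once per step, so the outcome is deterministic given positions and
the random stream.

Boundaries are open by default (no walls): by 1 μs the diffusion length
(~0.2 μm) is small compared with the transverse extent of the scoring
volume, and every molecule keeps counting toward N(t) wherever it
diffuses.  A cubic periodic box can be requested instead, which is what
the dilute well-mixed kinetics checks use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .analysis import GSeries
from .errors import ConfigError
from .reactions import ReactionTable
from .species import SpeciesTable


@dataclass
class TimestepSchedule:
    """Adaptive dt: ``dt_min`` early, one decade of dt per decade of elapsed
    time after ``growth_start``, capped at ``dt_max``.

    Elapsed time is measured from the last reset (simulation start or the
    activation of a delayed track); between resets dt is non-decreasing.
    """

    dt_min: float = 0.1  # ps (1e-13 s)
    dt_max: float = 10.0  # ps (1e-11 s)
    growth_start: float = 1.0e3  # ps of elapsed time before dt starts growing
    t_ref: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.dt_min <= self.dt_max:
            raise ConfigError("need 0 < dt_min <= dt_max")

    def dt(self, t: float) -> float:
        elapsed = t - self.t_ref
        if elapsed < self.growth_start:
            return self.dt_min
        decades = int(np.floor(np.log10(elapsed / self.growth_start))) + 1
        return min(self.dt_max, self.dt_min * 10.0**decades)

    def reset(self, t: float) -> None:
        self.t_ref = t


class SimulationState:
    """Mutable particle state of one chemical-stage run.

    Molecules are flat numpy arrays; the ``active`` flag implements the
    delayed-track freeze (inactive molecules never move, react, or count
    toward N(t)), and ``alive`` marks molecules not yet consumed.
    """

    def __init__(
        self,
        species_table: SpeciesTable,
        species: np.ndarray,
        pos: np.ndarray,
        track: np.ndarray,
        active: np.ndarray,
        time: float = 1.0,
        energy: float = 0.0,
    ):
        n = len(species)
        self.species_table = species_table
        self.species = np.asarray(species, dtype=np.int64)
        self.pos = np.array(pos, dtype=float)
        self.track = np.asarray(track, dtype=np.int64)
        self.active = np.array(active, dtype=bool)
        self.alive = np.ones(n, dtype=bool)
        self.t_create = np.full(n, time)
        self.time = float(time)
        self.energy = float(energy)
        self.energy_steps: list[tuple[float, float]] = [(float(time), float(energy))]
        ns = len(species_table)
        self.produced = np.zeros(ns, dtype=np.int64)
        self.consumed = np.zeros(ns, dtype=np.int64)
        self.reaction_log: list[tuple[float, int, float, float, float, int, int]] = []

    def __len__(self) -> int:
        return len(self.species)

    def counts(self, per_track: int | None = None) -> np.ndarray:
        """N per species over alive+active molecules (optionally one track)."""
        mask = self.alive & self.active
        if per_track is not None:
            mask &= self.track == per_track
        return np.bincount(self.species[mask], minlength=len(self.species_table))

    def add_energy(self, e: float) -> None:
        self.energy += e
        self.energy_steps.append((self.time, self.energy))

    def activate_track(self, tid: int) -> None:
        self.active |= self.track == tid

    def append_molecules(self, species, pos, track, time: float) -> None:
        k = len(species)
        self.species = np.concatenate([self.species, species])
        self.pos = np.concatenate([self.pos, pos])
        self.track = np.concatenate([self.track, track])
        self.active = np.concatenate([self.active, np.ones(k, dtype=bool)])
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        self.t_create = np.concatenate([self.t_create, np.full(k, time)])

    def composition_totals(self) -> tuple[int, int, int]:
        """(H, O, charge) carried by all alive molecules (frozen ones too)."""
        t = self.species_table
        c = np.bincount(self.species[self.alive], minlength=len(t))
        return int(c @ t.n_h), int(c @ t.n_o), int(c @ t.charge)


def state_from_inventories(inventories, active, time: float = 1.0) -> SimulationState:
    """Build a state from one or more 1-ps inventories.

    ``active`` is one bool per inventory; the energy of *inactive*
    inventories is not yet added to E(t) — it steps in at activation.
    """
    table = inventories[0].species_table
    species = np.concatenate([inv.species for inv in inventories])
    pos = np.concatenate([inv.pos for inv in inventories])
    track = np.concatenate([inv.track_id for inv in inventories])
    act = np.concatenate(
        [np.full(len(inv), a, dtype=bool) for inv, a in zip(inventories, active)]
    )
    energy = sum(inv.energy for inv, a in zip(inventories, active) if a)
    return SimulationState(table, species, pos, track, act, time, energy)


class ChemistryEngine:
    """Diffusion + reaction propagator bound to a species/reaction table."""

    def __init__(
        self,
        species: SpeciesTable,
        reactions: ReactionTable,
        schedule: TimestepSchedule | None = None,
        *,
        intertrack: bool = True,
        box: float | None = None,
        product_jitter: float = 0.0,
        verlet_skin: float = 12.0,
    ):
        self.species = species
        self.reactions = reactions
        self.schedule = schedule or TimestepSchedule()
        self.intertrack = intertrack
        self.box = box
        self.product_jitter = product_jitter
        self.skin = verlet_skin
        self._sigma_cache: dict[float, np.ndarray] = {}
        # relative diffusion coefficient per species pair, for the bridge test
        self._drel = species.d[:, None] + species.d[None, :]
        self._invalidate()

    # -------------------------------------------------------------- workspace
    #
    # Live, active molecules are mirrored into contiguous arrays so the hot
    # loop avoids boolean fancy indexing; the mirror is flushed back into the
    # state whenever composition changes (reaction, activation) or positions
    # are needed externally.

    def _invalidate(self, state: SimulationState | None = None) -> None:
        if state is not None and getattr(self, "_ws_idx", None) is not None:
            state.pos[self._ws_idx] = self._ws_pos
        self._ws_idx = None
        self._ws_pos = None
        self._ws_prev = None
        self._ws_species = None
        self._ci = None
        self._last_dt = 0.0
        self._budget = 0.0

    def _ensure_ws(self, state: SimulationState) -> None:
        if self._ws_idx is not None:
            return
        idx = np.flatnonzero(state.alive & state.active)
        self._ws_idx = idx
        self._ws_pos = np.array(state.pos[idx])
        self._ws_species = state.species[idx]
        self._ws_track = state.track[idx]
        self._ws_alive = np.ones(len(idx), dtype=bool)
        self._ws_sigma: dict[float, np.ndarray] = {}
        self._rebuild_pairs()

    def _rebuild_pairs(self) -> None:
        """Verlet candidate list over the workspace (open-boundary mode)."""
        self._ws_pos0 = np.array(self._ws_pos)
        reactive = self.reactions.reactive[self._ws_species] & self._ws_alive
        ridx = np.flatnonzero(reactive)
        if len(ridx) < 2:
            self._ci = np.empty(0, dtype=np.int64)
            self._cj = np.empty(0, dtype=np.int64)
            self._cr2 = np.empty(0)
            return
        if self.box is not None:
            tree = cKDTree(np.mod(self._ws_pos[ridx], self.box), boxsize=self.box)
        else:
            tree = cKDTree(self._ws_pos[ridx], balanced_tree=False, compact_nodes=False)
        pairs = tree.query_pairs(self.reactions.max_radius + self.skin, output_type="ndarray")
        wi = ridx[pairs[:, 0]]
        wj = ridx[pairs[:, 1]]
        if not self.intertrack:
            same = self._ws_track[wi] == self._ws_track[wj]
            wi, wj = wi[same], wj[same]
        r2 = self.reactions.radius_sq[self._ws_species[wi], self._ws_species[wj]]
        keep = r2 > 0.0
        ci, cj, cr2 = wi[keep], wj[keep], r2[keep]
        # Sort candidates by how much they must approach before they can
        # react (their "margin"): a pair whose margin exceeds twice the
        # largest accumulated displacement cannot be a hit yet, so each
        # step only the leading, small-margin slice needs distance checks.
        cr = np.sqrt(cr2)
        cdrel = self._drel[self._ws_species[ci], self._ws_species[cj]]
        db = self._ws_pos[ci] - self._ws_pos[cj]
        if self.box is not None:
            db -= self.box * np.round(db / self.box)
        reach = cr + 4.0 * np.sqrt(2.0 * cdrel * self.schedule.dt_max)
        margin = np.sqrt(np.einsum("ij,ij->i", db, db)) - reach
        order = np.argsort(margin, kind="stable")
        self._ci, self._cj = ci[order], cj[order]
        self._cr2, self._cr = cr2[order], cr[order]
        self._cdrel = cdrel[order]
        self._cmargin = np.maximum(margin[order], 0.0)
        self._hot = int(np.searchsorted(self._cmargin, 0.0, side="right"))
        self._cwin2_dt = None

    # -------------------------------------------------------------- operators

    def diffuse(self, state: SimulationState, dt: float, rng: np.random.Generator) -> None:
        """Brownian step: active molecules move, frozen ones do not."""
        if dt < 0:
            raise ConfigError("dt must be >= 0")
        if dt == 0.0:
            return
        self._ensure_ws(state)
        m = len(self._ws_idx)
        if m == 0:
            return
        sigma = self._ws_sigma.get(dt)
        if sigma is None:
            sigma = np.sqrt(2.0 * self.species.d * dt)[self._ws_species][:, None]
            self._ws_sigma[dt] = sigma
        if self._ws_prev is None or self._ws_prev.shape != self._ws_pos.shape:
            self._ws_prev = np.empty_like(self._ws_pos)
        np.copyto(self._ws_prev, self._ws_pos)
        self._last_dt = dt
        disp = rng.standard_normal((m, 3))
        disp *= sigma
        self._ws_pos += disp

    def react(self, state: SimulationState, rng: np.random.Generator) -> None:
        """Consume molecule pairs closer than their channel radius.

        Candidates are checked in increasing-distance order; each molecule
        reacts at most once per step.  Products appear at the pair
        midpoint (plus optional Gaussian jitter).
        """
        self._ensure_ws(state)
        # no pair outside the candidate list can have closed to within the
        # reaction radius while 2·max|Δx since build| stays below the skin
        dev = self._ws_pos - self._ws_pos0
        maxdev = float(np.sqrt(np.einsum("ij,ij->i", dev, dev).max(initial=0.0)))
        if 2.0 * maxdev > self.skin:
            self._rebuild_pairs()
            maxdev = 0.0
        if len(self._ci) == 0:
            return
        if maxdev > 0.0:
            # pairs whose margin exceeds 2·maxdev cannot be in reach yet
            grown = int(np.searchsorted(self._cmargin, 2.0 * maxdev, side="right"))
            if grown > self._hot:
                self._hot = grown
        hot = self._hot
        if hot == 0:
            return
        ci, cj, cr2 = self._ci[:hot], self._cj[:hot], self._cr2[:hot]
        d = self._ws_pos[ci] - self._ws_pos[cj]
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        d2 = np.einsum("ij,ij->i", d, d)
        hit = d2 <= cr2
        if self._ws_prev is not None and self._last_dt > 0.0:
            if self._cwin2_dt != self._last_dt:
                # crossing is only possible within a few relative step lengths
                self._cwin2 = (
                    self._cr + 4.0 * np.sqrt(2.0 * self._cdrel * self._last_dt)
                ) ** 2
                self._cwin2_dt = self._last_dt
            near = (~hit) & (d2 <= self._cwin2[:hot])
            if near.any():
                hit = hit | self._bridge_hits(ci, cj, d2, np.flatnonzero(near),
                                              self._cr[:hot], self._cdrel[:hot], rng)
        if not hit.any():
            return
        order = np.argsort(d2[hit], kind="stable")
        hi = ci[hit][order]
        hj = cj[hit][order]
        reacted = self._consume_pairs(state, hi, hj, self._ws_pos, rng,
                                      ws=True)
        if reacted:
            self._invalidate(state)

    def _bridge_hits(self, ci, cj, d2, near, cr, cdrel, rng) -> np.ndarray:
        """Sample which straddling candidate pairs crossed R mid-step."""
        out = np.zeros(len(ci), dtype=bool)
        d0v = self._ws_prev[ci[near]] - self._ws_prev[cj[near]]
        if self.box is not None:
            d0v -= self.box * np.round(d0v / self.box)
        d0 = np.sqrt(np.einsum("ij,ij->i", d0v, d0v))
        d1 = np.sqrt(d2[near])
        rr = cr[near]
        arg = (d0 - rr) * (d1 - rr) / (cdrel[near] * self._last_dt)
        p = np.exp(-np.maximum(arg, 0.0))  # d0 <= R counts as a sure crossing
        out[near] = rng.random(len(near)) < p
        return out

    def _consume_pairs(self, state, hi, hj, pos, rng, *, ws: bool) -> bool:
        """Greedy single-consumption reaction pass over ordered hit pairs."""
        rt = self.reactions
        reacted = False
        for i, j in zip(hi, hj):
            if ws:
                gi, gj = self._ws_idx[i], self._ws_idx[j]
                if not (self._ws_alive[i] and self._ws_alive[j]):
                    continue
                self._ws_alive[i] = False
                self._ws_alive[j] = False
            else:
                gi, gj = i, j
                if not (state.alive[gi] and state.alive[gj]):
                    continue
            a, b = state.species[gi], state.species[gj]
            c = rt.pick_channel(a, b, rng)
            state.alive[gi] = False
            state.alive[gj] = False
            state.consumed[a] += 1
            state.consumed[b] += 1
            delta = pos[i] - pos[j]
            if self.box is not None:
                delta -= self.box * np.round(delta / self.box)
                mid = np.mod(pos[j] + 0.5 * delta, self.box)
            else:
                mid = pos[j] + 0.5 * delta
            state.reaction_log.append(
                (state.time, int(c), float(mid[0]), float(mid[1]), float(mid[2]),
                 int(state.track[gi]), int(state.track[gj]))
            )
            prods = rt.product_idx[c]
            if len(prods):
                ppos = np.tile(mid, (len(prods), 1))
                if self.product_jitter > 0:
                    ppos = ppos + self.product_jitter * rng.standard_normal(ppos.shape)
                if ws:
                    # sync the two consumed positions before appending
                    state.pos[gi] = pos[i]
                    state.pos[gj] = pos[j]
                state.append_molecules(
                    prods,
                    ppos,
                    np.full(len(prods), state.track[gi], dtype=np.int64),
                    state.time,
                )
                state.produced[prods] += 1
            reacted = True
        return reacted

    def step(self, state: SimulationState, rng: np.random.Generator, dt: float | None = None) -> None:
        """One propagation step: diffuse, react, advance the clock."""
        if dt is None:
            dt = self.schedule.dt(state.time)
        self.diffuse(state, dt, rng)
        self.react(state, rng)
        state.time += dt

    # ----------------------------------------------------------------- evolve

    def evolve(
        self,
        state: SimulationState,
        t_end: float,
        log_times,
        rng: np.random.Generator,
        events: list[tuple[float, object]] | None = None,
    ) -> GSeries:
        """Propagate to ``t_end``, logging N(t), E(t) at each requested time.

        ``events`` is a list of (time, callback(state, engine)) executed
        exactly when the clock reaches that time, *before* any logging at
        the same instant — so a G-value logged at the activation time
        already includes the newly activated track.
        """
        log_times = np.asarray(sorted(set(float(t) for t in log_times)))
        if len(log_times) and (log_times[0] < state.time - 1e-9):
            raise ConfigError("log times must not precede the current state time")
        events = sorted(events or [], key=lambda e: e[0])
        stops = sorted(set(log_times.tolist()) | {t for t, _ in events} | {float(t_end)})
        log_set = set(log_times.tolist())

        n_tracks = int(state.track.max()) + 1 if len(state) else 1
        rec_t: list[float] = []
        rec_counts: list[np.ndarray] = []
        rec_energy: list[float] = []
        rec_track: list[np.ndarray] = []

        def log_now() -> None:
            rec_t.append(state.time)
            rec_counts.append(state.counts())
            rec_energy.append(state.energy)
            rec_track.append(
                np.stack([state.counts(per_track=k) for k in range(n_tracks)], axis=-1)
            )

        ev_i = 0
        for t_stop in stops:
            if t_stop > t_end + 1e-9:
                break
            while state.time < t_stop - 1e-9:
                dt = min(self.schedule.dt(state.time), t_stop - state.time)
                self.step(state, rng, dt)
            state.time = t_stop  # kill float drift at boundaries
            while ev_i < len(events) and events[ev_i][0] <= t_stop + 1e-9:
                events[ev_i][1](state, self)
                ev_i += 1
            if t_stop in log_set:
                log_now()

        self._invalidate(state)  # sync workspace positions back
        return GSeries(
            times=np.array(rec_t),
            species=self.species.labels,
            counts=np.array(rec_counts, dtype=np.int64),
            energy=np.array(rec_energy),
            track_counts=np.array(rec_track, dtype=np.int64),
        )


def check_conservation(
    initial_counts: np.ndarray,
    state: SimulationState,
    reactions: ReactionTable,
) -> tuple[int, int, int]:
    """(ΔH, ΔO, Δcharge) between the start and end of a run.

    All three are zero for a consistent engine: water emissions from the
    reaction log are added back to the surviving-molecule totals.
    """
    table = state.species_table
    h0 = int(initial_counts @ table.n_h)
    o0 = int(initial_counts @ table.n_o)
    q0 = int(initial_counts @ table.charge)
    h1, o1, q1 = state.composition_totals()
    n_h2o = sum(reactions.n_h2o[c] for _, c, *_ in state.reaction_log)
    return (h1 + 2 * n_h2o - h0, o1 + n_h2o - o0, q1 - q0)
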