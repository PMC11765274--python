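"""Reaction–diffusion engine: Brownian statistics, forced reactions,
timestep schedule, activation semantics and conservation."""

import numpy as np
import pytest

from intertrack import (
    ChemistryEngine,
    ConfigError,
    ReactionTable,
    SimulationState,
    SpeciesTable,
    TimestepSchedule,
    check_conservation,
    default_reaction_table,
    make_fixture,
    state_from_inventories,
)
from intertrack.reactions import ReactionChannel


def make_state(species_table, labels, pos, active=None, energy=100.0, track=None):
    n = len(labels)
    species = np.array([species_table.index[s] for s in labels])
    active = np.ones(n, dtype=bool) if active is None else np.asarray(active)
    track = np.zeros(n, dtype=np.int64) if track is None else np.asarray(track)
    return SimulationState(species_table, species, np.asarray(pos, dtype=float),
                           track, active, time=1.0, energy=energy)


@pytest.fixture
def engine(species, reactions):
    return ChemistryEngine(species, reactions)


class TestTimestepSchedule:
    def test_endpoint_values(self):
        s = TimestepSchedule(t_ref=0.0)
        assert s.dt(0.0) == 0.1
        assert s.dt(999.0) == 0.1
        assert s.dt(1.0e3) == 1.0
        assert s.dt(9.9e3) == 1.0
        assert s.dt(1.0e4) == 10.0
        assert s.dt(1.0e6) == 10.0  # capped at 10 ps

    def test_monotone_between_resets_and_bounded(self):
        s = TimestepSchedule(t_ref=1.0)
        ts = np.geomspace(1.0, 2e6, 300)
        dts = [s.dt(t) for t in ts]
        assert all(b >= a for a, b in zip(dts, dts[1:]))
        assert min(dts) >= s.dt_min and max(dts) <= s.dt_max

    def test_reset_restores_fast_sampling(self):
        s = TimestepSchedule(t_ref=1.0)
        assert s.dt(5.0e5) == 10.0
        s.reset(5.0e5)
        assert s.dt(5.0e5) == 0.1

    def test_invalid_bounds(self):
        with pytest.raises(ConfigError):
            TimestepSchedule(dt_min=1.0, dt_max=0.1)


class TestDiffuse:
    def test_zero_dt_leaves_positions(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH", "e_aq"], [[0, 0, 0], [5, 0, 0]])
        before = st.pos.copy()
        eng.diffuse(st, 0.0, rng)
        eng._invalidate(st)
        assert np.array_equal(st.pos, before)

    def test_displacement_variance_matches_2Ddt(self, rng):
        # D = 5e-3 nm^2/ps, dt = 0.1 ps -> per-axis variance 1e-3 nm^2
        table = SpeciesTable.from_dict({"OH": 5.0e-3})
        eng = ChemistryEngine(table, ReactionTable([], table))
        n = 100_000
        st = SimulationState(table, np.zeros(n, dtype=int), np.zeros((n, 3)),
                             np.zeros(n, dtype=int), np.ones(n, dtype=bool))
        eng.diffuse(st, 0.1, rng)
        eng._invalidate(st)
        var = st.pos.var(axis=0)
        # variance of the sample variance: 2 sigma^4 / n
        se = np.sqrt(2.0 * (1e-3) ** 2 / n)
        assert np.all(np.abs(var - 1e-3) < 4 * se)

    def test_inactive_molecules_never_move(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH", "OH"], [[0, 0, 0], [5, 0, 0]],
                        active=[True, False])
        eng.diffuse(st, 10.0, rng)
        eng._invalidate(st)
        assert np.array_equal(st.pos[1], [5.0, 0.0, 0.0])
        assert not np.array_equal(st.pos[0], [0.0, 0.0, 0.0])

    def test_negative_dt_rejected(self, engine, species, rng):
        st = make_state(species, ["OH"], [[0, 0, 0]])
        with pytest.raises(ConfigError):
            engine.diffuse(st, -1.0, rng)


class TestReact:
    def test_two_oh_within_radius_become_one_h2o2_at_midpoint(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH", "OH"], [[0, 0, 0], [0.1, 0, 0]])
        eng.react(st, rng)
        counts = st.counts()
        assert counts[species.index["OH"]] == 0
        assert counts[species.index["H2O2"]] == 1
        assert np.allclose(st.pos[-1], [0.05, 0.0, 0.0])

    def test_hydronium_electron_recombination_yields_h_atom(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["H3O+", "e_aq"], [[0, 0, 0], [0.05, 0, 0]])
        eng.react(st, rng)
        counts = st.counts()
        assert counts[species.index["H"]] == 1
        assert counts[species.index["H3O+"]] == 0
        assert counts[species.index["e_aq"]] == 0

    def test_pair_without_channel_never_reacts(self, species, reactions, rng):
        # no OH- + e_aq channel in the default set, even at zero distance
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH-", "e_aq"], [[0, 0, 0], [0, 0, 0]])
        eng.react(st, rng)
        assert st.counts().sum() == 2

    def test_frozen_molecules_do_not_react(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH", "OH"], [[0, 0, 0], [0.1, 0, 0]],
                        active=[True, False])
        eng.react(st, rng)
        assert st.counts()[species.index["OH"]] == 1  # only the active one counted
        assert st.alive.all()

    def test_each_molecule_consumed_at_most_once(self, species, reactions, rng):
        # three OH in a row: only the closest pair reacts this step
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH", "OH", "OH"],
                        [[0, 0, 0], [0.08, 0, 0], [0.2, 0, 0]])
        eng.react(st, rng)
        c = st.counts()
        assert c[species.index["H2O2"]] == 1
        assert c[species.index["OH"]] == 1

    def test_cross_track_reactions_suppressed_in_ni_mode(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions, intertrack=False)
        st = make_state(species, ["OH", "OH"], [[0, 0, 0], [0.05, 0, 0]],
                        track=[0, 1])
        eng.react(st, rng)
        assert st.counts()[species.index["OH"]] == 2


class TestEvolve:
    def test_empty_state_logs_zero_counts(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = SimulationState(species, np.empty(0, dtype=int), np.empty((0, 3)),
                             np.empty(0, dtype=int), np.empty(0, dtype=bool),
                             energy=100.0)
        series = eng.evolve(st, 100.0, [1.0, 10.0, 100.0], rng)
        assert series.counts.shape == (3, len(species))
        assert (series.counts == 0).all()

    def test_isolated_radical_survives_with_unit_count(self, species, reactions, rng):
        eng = ChemistryEngine(species, reactions)
        st = make_state(species, ["OH"], [[0, 0, 0]])
        series = eng.evolve(st, 1.0e4, np.geomspace(1, 1e4, 10), rng)
        assert (series.counts[:, species.index["OH"]] == 1).all()

    def test_conservation_over_a_mini_track(self, species, rng):
        reactions = default_reaction_table(species)
        inv = make_fixture("mini_track", seed=5, n=60, spacing=1.0)
        initial = inv.counts()
        st = state_from_inventories([inv], [True])
        eng = ChemistryEngine(species, reactions)
        eng.evolve(st, 1.0e4, [1.0e4], rng)
        assert len(st.reaction_log) > 0, "fixture should actually react"
        assert check_conservation(initial, st, reactions) == (0, 0, 0)

    def test_seeded_runs_are_identical(self, species, reactions):
        inv = make_fixture("mini_track", seed=3, n=30, spacing=1.5)
        out = []
        for _ in range(2):
            st = state_from_inventories([inv], [True])
            eng = ChemistryEngine(species, reactions)
            series = eng.evolve(st, 2.0e3, np.geomspace(1, 2e3, 8),
                                np.random.default_rng(77))
            out.append(series)
        assert np.array_equal(out[0].counts, out[1].counts)
        assert np.array_equal(out[0].energy, out[1].energy)

    def test_pair_survival_matches_smoluchowski_formula(self, species, rng):
        """Isolated reactive pair: P(react by t->inf) = R / r0.

        Uses a lattice of well-separated pairs evolved in one state; the
        closed-form ultimate reaction probability is the oracle for the
        diffusion–reaction coupling (smaller version of the acceptance
        check).
        """
        from intertrack.reactions import smoluchowski_radius

        d = 5.0e-3
        table = SpeciesTable.from_dict({"H3O+": d, "e_aq": d, "H": d})
        k = 0.5 * 4.0 * np.pi * (2 * d) / 1.6606e-12  # R = 0.5 nm
        rt = ReactionTable([ReactionChannel(("H3O+", "e_aq"), ("H",), k)], table)
        assert rt.radius[0] == pytest.approx(0.5, rel=1e-12)
        n_pairs, r0 = 1500, 1.0
        pos = np.zeros((2 * n_pairs, 3))
        pos[0::2, 0] = np.arange(n_pairs) * 1.0e4
        pos[1::2, 0] = np.arange(n_pairs) * 1.0e4 + r0
        species_arr = np.tile([0, 1], n_pairs)
        st = SimulationState(table, species_arr, pos,
                             np.zeros(2 * n_pairs, dtype=int),
                             np.ones(2 * n_pairs, dtype=bool))
        eng = ChemistryEngine(table, rt)
        eng.evolve(st, 3.0e4, [3.0e4], rng)
        frac = len(st.reaction_log) / n_pairs
        # finite-time correction: W(t) = (R/r0) erfc((r0-R)/sqrt(4 D_rel t))
        from scipy.special import erfc
        expected = 0.5 * erfc(0.5 / np.sqrt(4 * 2 * d * 3.0e4))
        se = np.sqrt(expected * (1 - expected) / n_pairs)
        assert abs(frac - expected) < 3.5 * se
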