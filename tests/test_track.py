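"""Track-surrogate sampling: event statistics, prechemistry, bookkeeping."""

import numpy as np
import pytest

from intertrack import ConfigError, apply_prechemistry, generate_track, sample_primary_events
from intertrack.track import (
    BranchingTable,
    EventSet,
    ParticleSpec,
    PrechemChannel,
    RadialProfile,
)

SPEC = ParticleSpec("carbon", 240.0, 30.0, 2.0)


class TestParticleSpec:
    def test_total_energy_is_let_times_depth(self):
        assert SPEC.total_energy_ev == pytest.approx(60000.0)

    @pytest.mark.parametrize("bad", [dict(let=-1), dict(depth=0), dict(energy=0)])
    def test_nonpositive_parameters_rejected(self, bad):
        kw = dict(name="p", energy=20.0, let=30.0, depth=2.0)
        kw.update(bad)
        with pytest.raises(ConfigError):
            ParticleSpec(**kw)


class TestPrimaryEvents:
    def test_event_count_mean(self):
        # mean = 60000 / 62.5 = 960; check the empirical mean over many seeds.
        # Clustering (Poisson(1) events per spur here) doubles the count
        # variance relative to a plain Poisson process.
        n_seeds = 500
        counts = [
            len(sample_primary_events(SPEC, 62.5, np.random.default_rng(s)))
            for s in range(n_seeds)
        ]
        se = np.sqrt(2.0 * 960.0 / n_seeds)
        assert abs(np.mean(counts) - 960.0) < 3 * se

    def test_energy_expectation(self, rng):
        ev = sample_primary_events(SPEC, 62.5, rng)
        # each event carries the mean event energy exactly
        assert ev.energy.sum() == pytest.approx(len(ev) * 62.5)

    def test_events_lie_near_the_scoring_depth(self, rng):
        # spur centres are confined to [0, depth]; events scatter ~1 nm around
        ev = sample_primary_events(SPEC, 62.5, rng)
        assert (ev.pos[:, 2] >= -10.0).all() and (ev.pos[:, 2] <= 2010.0).all()

    def test_zero_width_profile_puts_events_on_axis(self, rng):
        radial = RadialProfile(core_sigma=0.0, tail_fraction=0.0, spur_sigma=0.0)
        ev = sample_primary_events(SPEC, 62.5, rng, radial=radial)
        assert np.allclose(ev.pos[:, :2], 0.0)

    def test_bad_mean_event_energy(self, rng):
        with pytest.raises(ConfigError):
            sample_primary_events(SPEC, 0.0, rng)


def _events(kinds, pos=None, energy=62.5):
    kinds = np.asarray(kinds, dtype=object)
    n = len(kinds)
    pos = np.zeros((n, 3)) if pos is None else pos
    return EventSet(kinds, pos, np.full(n, energy))


class TestPrechemistry:
    def test_deterministic_ionization_channel_yields_three_products(self, species, rng):
        table = BranchingTable(
            {"ionization": [PrechemChannel(("OH", "H3O+", "e_aq"), 1.0, (0, 0, 0))]},
            species,
        )
        inv = apply_prechemistry(_events(["ionization"]), table, rng)
        assert len(inv) == 3
        assert inv.energy == pytest.approx(62.5)

    def test_zero_events_gives_empty_inventory(self, species, rng):
        table = BranchingTable(species=species)
        inv = apply_prechemistry(_events([]), table, rng)
        assert len(inv) == 0 and inv.energy == 0.0

    def test_channel_counts_are_binomial(self, species, rng):
        table = BranchingTable(
            {
                "ionization": [
                    PrechemChannel(("OH",), 0.7, (0.0,)),
                    PrechemChannel(("H",), 0.3, (0.0,)),
                ]
            },
            species,
        )
        inv = apply_prechemistry(_events(["ionization"] * 1000), table, rng)
        n_oh = int((inv.species == species.index["OH"]).sum())
        assert abs(n_oh - 700) < 3 * np.sqrt(1000 * 0.7 * 0.3)

    def test_zero_displacement_scale_keeps_products_at_event(self, species, rng):
        table = BranchingTable(
            {"ionization": [PrechemChannel(("OH", "e_aq", "H3O+"), 1.0, (0, 0, 0))]},
            species,
        )
        pos = rng.normal(size=(5, 3))
        inv = apply_prechemistry(_events(["ionization"] * 5, pos=pos), table, rng)
        for p in inv.pos:
            assert any(np.allclose(p, q) for q in pos)

    def test_unknown_event_class_is_an_error(self, species, rng):
        table = BranchingTable(species=species)
        with pytest.raises(ConfigError):
            apply_prechemistry(_events(["nuclear"]), table, rng)

    def test_probabilities_must_sum_to_one(self, species):
        with pytest.raises(ConfigError):
            BranchingTable(
                {"ionization": [PrechemChannel(("OH",), 0.5, (0.0,))]}, species
            )


class TestGenerateTrack:
    def test_same_seed_identical_inventories(self):
        branching = BranchingTable()
        a = generate_track(SPEC, branching, 42)
        b = generate_track(SPEC, branching, 42)
        assert np.array_equal(a.species, b.species)
        assert np.array_equal(a.pos, b.pos)
        assert a.energy == b.energy

    def test_molecule_count_scales_with_let(self):
        branching = BranchingTable()
        spec2 = ParticleSpec("carbon", 240.0, 60.0, 2.0)
        n1 = np.mean([len(generate_track(SPEC, branching, s)) for s in range(30)])
        n2 = np.mean([len(generate_track(spec2, branching, s + 100)) for s in range(30)])
        # doubling LET doubles the expected event (hence molecule) count
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_initial_yield_matches_branching_expectation(self, species):
        branching = BranchingTable(species=species)
        counts = np.zeros(len(species))
        n_rep, w = 40, 62.5
        for s in range(n_rep):
            counts += generate_track(SPEC, branching, s, mean_event_energy=w).counts()
        counts /= n_rep
        expected = (SPEC.total_energy_ev / w) * branching.expected_yield(
            {"ionization": 0.75, "excitation": 0.25}
        )
        for i, lab in enumerate(species.labels):
            if expected[i] == 0:
                assert counts[i] == 0
            else:
                # thinned clustered events: allow the clustering overdispersion
                se = np.sqrt(2.0 * expected[i] / n_rep)
                assert abs(counts[i] - expected[i]) < 4 * se, lab

    def test_energy_bookkeeping_is_exact(self):
        inv = generate_track(SPEC, BranchingTable(), 7, mean_event_energy=16.7)
        # deposited energy is an integer number of per-event quanta
        n_events = inv.energy / 16.7
        assert n_events == pytest.approx(round(n_events), abs=1e-9)
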