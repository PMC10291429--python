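"""Birth–death simulator: initialization, reproduction, insertion, mortality."""

import numpy as np
import pytest
from scipy import stats

from hierdyn import inequality, society
from hierdyn.society import Individual, Inheritance, SimConfig, SocietyState


def make_state(n, mothers=None, births=None):
    mothers = mothers or [None] * n
    births = births or [0] * n
    roster = [
        Individual(id=k, mother_id=mothers[k], birth_update=births[k]) for k in range(n)
    ]
    return SocietyState(roster=roster, update_counter=max(births))


class TestInitialize:
    def test_thirty_founders_without_mothers(self):
        state = society.initialize_society(SimConfig(n=30), np.random.default_rng(0))
        assert state.size == 30
        assert all(ind.mother_id is None for ind in state.roster)
        assert sorted(ind.id for ind in state.roster) == list(range(30))

    def test_smallest_group(self):
        state = society.initialize_society(SimConfig(n=2), np.random.default_rng(0))
        assert {ind.id for ind in state.roster} == {0, 1}

    def test_deterministic_under_fixed_seed(self):
        a = society.initialize_society(SimConfig(n=30), np.random.default_rng(7))
        b = society.initialize_society(SimConfig(n=30), np.random.default_rng(7))
        assert [i.id for i in a.roster] == [i.id for i in b.roster]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n=1)

    def test_founder_order_is_uniform(self):
        rng = np.random.default_rng(3)
        top = [
            society.initialize_society(SimConfig(n=4), rng).roster[0].id
            for _ in range(4000)
        ]
        counts = np.bincount(top, minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01


class TestChooseReproducer:
    def selection_counts(self, config, n_draws=100_000, seed=0):
        rng = np.random.default_rng(seed)
        state = make_state(config.n)
        counts = np.zeros(config.n)
        for _ in range(n_draws):
            counts[society.choose_reproducer(state, config, rng).id] += 1
        return counts / n_draws

    def test_uniform_without_rank_effect(self):
        freqs = self.selection_counts(SimConfig(n=30, rank_effect=False))
        se = np.sqrt((1 / 30) * (29 / 30) / 100_000)
        assert np.all(np.abs(freqs - 1 / 30) < 3.5 * se)

    def test_zero_slope_degenerates_to_uniform(self):
        freqs = self.selection_counts(SimConfig(n=30, rank_effect=True, reproduction_slope=0.0))
        se = np.sqrt((1 / 30) * (29 / 30) / 100_000)
        assert np.all(np.abs(freqs - 1 / 30) < 3.5 * se)

    def test_top_bottom_ratio_matches_weights(self, slope):
        freqs = self.selection_counts(SimConfig(n=30, rank_effect=True), n_draws=200_000)
        w = inequality.reproduction_weights(30, slope)
        expected_ratio = w.w[0] / w.w[-1]
        assert freqs[0] / freqs[-1] == pytest.approx(expected_ratio, rel=0.1)


class TestInsertOffspring:
    def test_mri_queen_offspring_lands_second(self):
        state = make_state(5)
        out = society.insert_offspring(
            state, state.roster[0], Inheritance.MRI_YA, np.random.default_rng(0)
        )
        assert out.roster[1].mother_id == state.roster[0].id
        assert out.size == 6

    def test_mri_directly_below_mother(self):
        state = make_state(5)
        out = society.insert_offspring(
            state, state.roster[3], Inheritance.MRI_YA, np.random.default_rng(0)
        )
        assert out.roster[4].mother_id == state.roster[3].id

    def test_primogeniture_below_youngest_older_sibling(self):
        # mother at position 4 (index 3); older siblings at positions 5 and 6
        mothers = [None, None, None, None, 3, 3, None]
        births = [0, 0, 0, 0, 1, 2, 0]
        state = make_state(7, mothers, births)
        out = society.insert_offspring(
            state, state.roster[3], Inheritance.PRIMOGENITURE, np.random.default_rng(0)
        )
        # offspring directly below the youngest older sibling -> position 7
        assert out.roster[6].mother_id == 3
        assert out.roster[6].birth_update == 3

    def test_primogeniture_without_siblings_matches_mri(self):
        state = make_state(5)
        out = society.insert_offspring(
            state, state.roster[2], Inheritance.PRIMOGENITURE, np.random.default_rng(0)
        )
        assert out.roster[3].mother_id == 2

    def test_correlation_half_above_and_always_adjacent(self):
        rng = np.random.default_rng(0)
        n_above = 0
        n_draws = 100_000
        state = make_state(6)
        mother = state.roster[2]
        for _ in range(n_draws):
            out = society.insert_offspring(state, mother, Inheritance.CORRELATION, rng)
            child_idx = next(
                k for k, ind in enumerate(out.roster) if ind.mother_id == mother.id
            )
            mother_idx = next(k for k, ind in enumerate(out.roster) if ind.id == mother.id)
            assert abs(child_idx - mother_idx) == 1
            n_above += child_idx < mother_idx
        se = np.sqrt(0.25 / n_draws)
        assert abs(n_above / n_draws - 0.5) < 3 * se

    def test_random_placement_is_uniform_over_slots(self):
        rng = np.random.default_rng(0)
        state = make_state(6)
        mother = state.roster[0]
        counts = np.zeros(7)
        for _ in range(20_000):
            out = society.insert_offspring(state, mother, Inheritance.NONE, rng)
            child_idx = next(
                k for k, ind in enumerate(out.roster) if ind.mother_id == mother.id
            )
            counts[child_idx] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_unknown_mother_rejected(self):
        state = make_state(4)
        stranger = Individual(id=99, mother_id=None, birth_update=0)
        with pytest.raises(ValueError):
            society.insert_offspring(state, stranger, Inheritance.MRI_YA, np.random.default_rng(0))


class TestMortality:
    def test_group_returns_to_size_n(self):
        rng = np.random.default_rng(0)
        state = make_state(30)
        newborn = Individual(id=100, mother_id=0, birth_update=1)
        grown = society.insert_offspring(state, state.roster[0], Inheritance.MRI_YA, rng, newborn)
        shrunk = society.apply_mortality(grown, rng, newborn)
        assert shrunk.size == 30

    def test_newborn_exempt_and_removal_uniform(self):
        rng = np.random.default_rng(0)
        removal_counts = np.zeros(30)
        n_trials = 50_000
        for _ in range(n_trials):
            state = make_state(30)
            newborn = Individual(id=100, mother_id=0, birth_update=1)
            grown = society.insert_offspring(
                state, state.roster[0], Inheritance.MRI_YA, rng, newborn
            )
            shrunk = society.apply_mortality(grown, rng, newborn)
            assert any(ind.id == 100 for ind in shrunk.roster)
            (dead,) = set(range(30)) - {i.id for i in shrunk.roster}
            removal_counts[dead] += 1
        assert stats.chisquare(removal_counts).pvalue > 0.01


class TestRunSimulation:
    def test_constant_group_size_and_snapshot_shape(self):
        cfg = SimConfig(n=30, n_updates=50, burn_in=10, n_replicates=3, seed=5)
        rec = society.run_simulation(cfg)
        assert rec.positions.shape == (3, 50, 30)
        for r in range(3):
            for t in range(50):
                assert len(set(rec.positions[r, t])) == 30

    def test_mri_offspring_adjacent_below_mother_at_birth(self):
        cfg = SimConfig(
            n=30, inheritance=Inheritance.MRI_YA, n_updates=100, burn_in=10,
            n_replicates=2, seed=5,
        )
        rec = society.run_simulation(cfg)
        for r in range(2):
            for t in range(1, 101):
                newborn = 30 + t - 1
                snap = list(rec.positions[r, t - 1])
                mother = rec.mothers[r, newborn]
                if mother in snap:
                    # unless the mother died this update, the same-update death
                    # elsewhere cannot separate an adjacent pair
                    assert snap.index(newborn) == snap.index(mother) + 1

    def test_bit_identical_under_same_seed(self):
        cfg = SimConfig(n=30, n_updates=60, burn_in=10, n_replicates=2, seed=9)
        a, b = society.run_simulation(cfg), society.run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.mothers, b.mothers)

    def test_lifespan_independent_of_birth_rank_without_rank_effect(self):
        # with uniform mortality and no rank effect, when you die cannot
        # depend on where you entered the hierarchy
        cfg = SimConfig(
            n=30, inheritance=Inheritance.NONE, rank_effect=False,
            n_updates=1200, burn_in=0, n_replicates=20, seed=13,
        )
        rec = society.run_simulation(cfg)
        birth_ranks, lifespans = [], []
        for r in range(rec.n_replicates):
            present = np.zeros((cfg.n_updates, cfg.n + cfg.n_updates), dtype=bool)
            idx = np.arange(cfg.n_updates)[:, None]
            present[idx, rec.positions[r]] = True
            for ind in range(cfg.n, cfg.n + cfg.n_updates):
                alive = np.flatnonzero(present[:, ind])
                if alive.size == 0 or present[-1, ind]:
                    continue  # died at birth or censored at the end
                birth_t = rec.births[r, ind]
                birth_ranks.append(int(np.where(rec.positions[r, birth_t - 1] == ind)[0][0]))
                lifespans.append(alive.size)
        slope_fit = stats.linregress(birth_ranks, lifespans)
        # slope in updates per position; mean lifespan ~30 updates
        assert abs(slope_fit.slope) < 3 * slope_fit.stderr + 0.05

    def test_panel_export_round_trip_positions(self):
        cfg = SimConfig(n=5, n_updates=8, burn_in=2, n_replicates=2, seed=3)
        rec = society.run_simulation(cfg)
        df = rec.to_frame()
        assert len(df) == 2 * 8 * 5
        sub = df[(df["replicate"] == 1) & (df["update"] == 8)].sort_values("position")
        assert list(sub["id"]) == list(rec.positions[1, 7])
        assert sub["stdrank"].iloc[0] == 1.0 and sub["stdrank"].iloc[-1] == 0.0
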