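import numpy as np
import pytest

from cswolf import BudgetExhausted, Population, rank_leaders
from cswolf.idgwo import (
    encircle_candidate,
    gwo_linear_control,
    gwo_update,
    idgwo_position_update,
)


def make_pop(positions, fitness, fe_budget=10**6):
    positions = np.asarray(positions, dtype=float)
    return Population(
        positions=positions,
        fitness=np.asarray(fitness, dtype=float),
        fe_count=len(fitness),
        fe_budget=fe_budget,
    )


class HalfRng:
    """r1 = r2 = 0.5 per dimension -> A = 0, C = 1."""

    def uniform(self, size=None):
        return np.full(size, 0.5)


class TestEncircle:
    def test_zero_A_collapses_onto_leader(self, unit_square):
        cand = encircle_candidate(np.array([0.1, 0.9]), np.array([0.4, 0.2]), 1.0, unit_square, HalfRng())
        assert cand == pytest.approx([0.4, 0.2])

    def test_a_zero_collapses_for_any_draw(self, unit_square, rng):
        leader = np.array([0.3, 0.8])
        cand = encircle_candidate(rng.uniform(size=2), leader, 0.0, unit_square, rng)
        assert cand == pytest.approx(leader)

    def test_hand_computed_candidate(self):
        from cswolf import ObjectiveSpec

        box = ObjectiveSpec(d=1, lower=[-10], upper=[10], func=lambda x, r: 0.0)

        class Pinned:
            calls = 0

            def uniform(self, size=None):
                Pinned.calls += 1
                return np.array([1.0]) if Pinned.calls == 1 else np.array([0.5])

        # x=2, leader=1, a=1: A=1, C=1, D=|1-2|=1, candidate = 1 - 1 = 0
        cand = encircle_candidate(np.array([2.0]), np.array([1.0]), 1.0, box, Pinned())
        assert cand == pytest.approx([0.0])


class TestIdgwoUpdate:
    def setup_pop(self, unit_square):
        pop = make_pop(np.linspace(0.1, 0.8, 8).reshape(4, 2), [0.1, 0.2, 0.3, 0.9])
        leaders = rank_leaders(pop)
        lp = pop.positions[[leaders.alpha, leaders.beta, leaders.delta]].copy()
        return pop, leaders, lp

    def test_chooses_min_of_three_candidates(self, unit_square, rng):
        """Over random populations the replacement fitness equals the
        brute-force minimum of the three evaluated candidates."""
        for _ in range(200):
            pop, leaders, lp = self.setup_pop(unit_square)
            fe_before = pop.fe_count
            idgwo_position_update(pop, 3, leaders, lp, 0.7, unit_square, rng)
            assert pop.fe_count == fe_before + 3
            # recompute: replacement fitness must equal objective at new position
            assert pop.fitness[3] == pytest.approx(float(np.sum(pop.positions[3] ** 2)))

    def test_oracle_min_with_pinned_candidates(self, unit_square, rng, monkeypatch):
        import cswolf.idgwo as mod

        for _ in range(300):
            pop, leaders, lp = self.setup_pop(unit_square)
            cands = rng.uniform(size=(3, 2))
            it = iter(cands)
            monkeypatch.setattr(
                mod, "encircle_candidate", lambda *a, **k: next(it)
            )
            idgwo_position_update(pop, 3, leaders, lp, 0.7, unit_square, rng)
            fits = np.sum(cands**2, axis=1)
            assert pop.fitness[3] == pytest.approx(fits.min())

    def test_tie_keeps_first_candidate(self, unit_square, rng, monkeypatch):
        import cswolf.idgwo as mod

        same = np.array([0.25, 0.25])
        monkeypatch.setattr(mod, "encircle_candidate", lambda *a, **k: same.copy())
        pop, leaders, lp = self.setup_pop(unit_square)
        chosen = idgwo_position_update(pop, 3, leaders, lp, 0.7, unit_square, rng)
        assert chosen == 0

    def test_replacement_may_worsen_without_elitism(self, unit_square, monkeypatch):
        import cswolf.idgwo as mod

        bad = np.array([0.9, 0.9])
        monkeypatch.setattr(mod, "encircle_candidate", lambda *a, **k: bad.copy())
        pop, leaders, lp = self.setup_pop(unit_square)
        pop.fitness[3] = 0.0  # incumbent better than any candidate
        idgwo_position_update(pop, 3, leaders, lp, 0.7, unit_square, None)
        assert pop.fitness[3] > 0.0  # unconditional replacement

    def test_elitist_flag_keeps_better_incumbent(self, unit_square, monkeypatch):
        import cswolf.idgwo as mod

        bad = np.array([0.9, 0.9])
        monkeypatch.setattr(mod, "encircle_candidate", lambda *a, **k: bad.copy())
        pop, leaders, lp = self.setup_pop(unit_square)
        pop.fitness[3] = 0.0
        chosen = idgwo_position_update(pop, 3, leaders, lp, 0.7, unit_square, None, elitist=True)
        assert chosen == -1 and pop.fitness[3] == 0.0

    def test_a_zero_lands_on_best_leader(self, unit_square, rng):
        pop, leaders, lp = self.setup_pop(unit_square)
        idgwo_position_update(pop, 3, leaders, lp, 0.0, unit_square, rng)
        leader_fits = [float(np.sum(p**2)) for p in lp]
        assert pop.fitness[3] == pytest.approx(min(leader_fits))

    def test_budget_gate_is_atomic(self, unit_square, rng):
        pop, leaders, lp = self.setup_pop(unit_square)
        pop.fe_budget = pop.fe_count + 2  # room for only 2 of 3 evaluations
        before = pop.positions[3].copy()
        with pytest.raises(BudgetExhausted):
            idgwo_position_update(pop, 3, leaders, lp, 0.5, unit_square, rng)
        assert np.array_equal(pop.positions[3], before)


class TestStandardGwo:
    def test_identical_candidates_average_to_themselves(self, unit_square, monkeypatch):
        import cswolf.idgwo as mod

        v = np.array([0.3, 0.6])
        monkeypatch.setattr(mod, "encircle_candidate", lambda *a, **k: v.copy())
        cand = gwo_update(np.array([0.5, 0.5]), np.zeros((3, 2)), 1.0, unit_square, None)
        assert cand == pytest.approx(v)

    def test_hand_computed_average(self, unit_square, monkeypatch):
        import cswolf.idgwo as mod

        cands = iter([np.array([0.0, 0.9]), np.array([0.9, 0.0]), np.array([0.0, 0.0])])
        monkeypatch.setattr(mod, "encircle_candidate", lambda *a, **k: next(cands))
        cand = gwo_update(np.array([0.5, 0.5]), np.zeros((3, 2)), 1.0, unit_square, None)
        assert cand == pytest.approx([0.3, 0.3])

    def test_linear_schedule(self):
        assert gwo_linear_control(0, 200) == 2.0
        assert gwo_linear_control(100, 200) == 1.0
        assert gwo_linear_control(0, 1) == 2.0  # single-iteration run keeps a = 2
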