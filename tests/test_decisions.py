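"""Pareto dominance, the non-dominated front, feasibility, NNIA archive."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openwindow import (
    DecisionContext,
    DecisionVector,
    ParetoArchive,
    decide_action,
    dominates,
    feasible,
    nnia_update,
    nondominated_front,
)
from openwindow.decisions import _allocate_clones, action_objectives


def brute_force_front(points):
    """O(n^2) double-loop oracle for the non-dominated set."""
    pts = np.asarray(points, float)
    out = []
    for j in range(len(pts)):
        if not any(dominates(pts[i], pts[j]) for i in range(len(pts)) if i != j):
            out.append(j)
    return out


vectors = st.lists(st.integers(-5, 5), min_size=2, max_size=4)


class TestDominance:
    def test_componentwise_examples(self):
        assert dominates([1, 2], [2, 3])
        assert not dominates([1, 3], [2, 2])
        assert not dominates([2, 2], [1, 3])
        assert not dominates([1, 2], [1, 2])  # irreflexive

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dominates([1, 2], [1, 2, 3])

    @given(a=vectors, b=vectors, c=vectors)
    @settings(max_examples=300, deadline=None)
    def test_strict_partial_order(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        assert not dominates(a, a)
        if dominates(a, b):
            assert not dominates(b, a)
        if dominates(a, b) and dominates(b, c):
            assert dominates(a, c)


class TestNondominatedFront:
    def test_simple_front(self):
        assert nondominated_front([[0, 1], [1, 0], [1, 1]]) == [0, 1]

    def test_identical_points_all_kept(self):
        assert nondominated_front([[2, 2]] * 4) == [0, 1, 2, 3]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        dims = int(rng.integers(2, 5))
        pts = rng.normal(size=(n, dims))
        assert nondominated_front(pts) == brute_force_front(pts)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nondominated_front([])


class TestFeasibility:
    def test_rest_always_feasible(self):
        ctx = DecisionContext(0, local_glucose=0.0, lactate=99.0, energy=0.0)
        assert feasible(DecisionVector("rest"), ctx)

    def test_proliferation_needs_glucose(self):
        ctx = DecisionContext(2, local_glucose=3.0, lactate=0.0, energy=9.0)
        assert not feasible(DecisionVector("proliferate"), ctx)  # cost 4 > 3

    def test_lactate_boundary_closed_against_proliferation(self):
        at = DecisionContext(2, local_glucose=9.0, lactate=7.0, energy=9.0)
        below = DecisionContext(2, local_glucose=9.0, lactate=6.999, energy=9.0)
        assert not feasible(DecisionVector("proliferate"), at)
        assert feasible(DecisionVector("proliferate"), below)

    def test_glucose_boundary_is_feasible(self):
        ctx = DecisionContext(1, local_glucose=0.4, lactate=0.0, energy=5.0)
        assert feasible(DecisionVector("attack"), ctx)  # g_i(x) == 0 allowed


class TestDecideAction:
    def test_infection_with_resources_triggers_defense(self):
        ctx = DecisionContext(3, local_glucose=10.0, lactate=0.0, energy=10.0)
        action = decide_action(ctx, np.random.default_rng(0)).action
        assert action in ("attack", "proliferate")

    def test_never_proliferates_under_suppressive_lactate(self):
        rng = np.random.default_rng(12)
        for _ in range(2000):
            ctx = DecisionContext(
                pathogens_in_radius=int(rng.integers(0, 8)),
                local_glucose=float(rng.uniform(0, 12)),
                lactate=float(rng.uniform(7.0, 20.0)),
                energy=float(rng.uniform(0, 10)),
            )
            assert decide_action(ctx, rng).action != "proliferate"

    def test_quiet_context_rests(self):
        ctx = DecisionContext(0, local_glucose=10.0, lactate=0.0, energy=10.0)
        assert decide_action(ctx, np.random.default_rng(0)).action in ("rest", "migrate")

    def test_always_feasible(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            ctx = DecisionContext(
                pathogens_in_radius=int(rng.integers(0, 8)),
                local_glucose=float(rng.uniform(0, 12)),
                lactate=float(rng.uniform(0, 20)),
                energy=float(rng.uniform(0, 10)),
            )
            assert feasible(decide_action(ctx, rng), ctx)


class TestNniaArchive:
    def _member(self, f, action="attack", intensity=1.0):
        return (DecisionVector(action, intensity), tuple(f))

    def test_dominated_candidates_leave_archive_unchanged(self):
        archive = ParetoArchive(members=[self._member([0, 1]), self._member([1, 0])])
        new, clones = nnia_update(
            archive, [self._member([2, 2]), self._member([3, 1])], rng=np.random.default_rng(0)
        )
        assert sorted(f for _, f in new.members) == [(0, 1), (1, 0)]
        assert len(clones) == 10

    def test_clone_allocation_sums_to_budget(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            iso = rng.uniform(0, 1, int(rng.integers(1, 8)))
            budget = int(rng.integers(1, 30))
            counts = _allocate_clones(iso, budget)
            assert counts.sum() == budget

    def test_isolated_member_gets_majority_of_clones(self):
        # two crowded members and one far-off member: the isolated one
        # must receive at least half the budget
        archive = ParetoArchive(
            members=[
                self._member([0.0, 1.0]),
                self._member([0.01, 0.99]),
                self._member([1.0, 0.0]),
            ]
        )
        new, clones = nnia_update(archive, [], clone_budget=10, mutation_scale=0.0,
                                  rng=np.random.default_rng(0))
        from collections import Counter
        per_member = Counter()
        iso = new.crowding()
        counts = _allocate_clones(iso, 10)
        assert counts[2] >= 5

    def test_zero_mutation_clones_are_exact_copies(self):
        archive = ParetoArchive(members=[self._member([0, 0], intensity=0.7)])
        _, clones = nnia_update(archive, [], mutation_scale=0.0, rng=np.random.default_rng(0))
        assert all(c.intensity == 0.7 for c in clones)

    def test_mutated_intensities_stay_in_unit_interval(self):
        archive = ParetoArchive(members=[self._member([0, 0], intensity=0.95)])
        _, clones = nnia_update(
            archive, [], clone_budget=200, mutation_scale=0.5, rng=np.random.default_rng(1)
        )
        assert all(0.0 <= c.intensity <= 1.0 for c in clones)

    def test_truncation_to_max_size(self):
        rng = np.random.default_rng(3)
        # points on a line with negative slope are mutually non-dominated
        cands = [self._member([i / 40, 1 - i / 40]) for i in range(40)]
        archive, _ = nnia_update(ParetoArchive(max_size=5), cands, rng=rng)
        assert len(archive.members) == 5

    def test_archive_never_holds_dominated_pair(self):
        rng = np.random.default_rng(8)
        archive = ParetoArchive(max_size=10)
        for _ in range(200):
            cands = [
                self._member(rng.normal(size=2)) for _ in range(int(rng.integers(1, 6)))
            ]
            archive, _ = nnia_update(archive, cands, rng=rng)
            pts = archive.objective_matrix()
            for i in range(len(pts)):
                for j in range(len(pts)):
                    if i != j:
                        assert not dominates(pts[i], pts[j])


class TestObjectives:
    def test_attack_value_scales_with_targets(self):
        ctx = DecisionContext(4, local_glucose=10.0, lactate=0.0, energy=10.0, kill_weight=0.5)
        f1, f2 = action_objectives(DecisionVector("attack"), ctx)
        assert f1 == pytest.approx(-2.0)
        assert f2 == pytest.approx(ctx.attack_cost)

    def test_rest_is_free(self):
        ctx = DecisionContext(4, local_glucose=10.0, lactate=0.0, energy=10.0)
        assert action_objectives(DecisionVector("rest"), ctx) == (0.0, 0.0)
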