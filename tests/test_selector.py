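"""Annealed minimum-set selection vs hand arithmetic and enumeration."""

import numpy as np
import pandas as pd
import pytest

from reserva.landscape import (FeatureAmountMatrix, GridSpec, PlanningUnitSet,
                               PUStatus)
from reserva.selector import (AnnealSchedule, SelectionProblem, anneal,
                              brute_force_optimum, greedy_add_baseline,
                              objective, priority_areas, summed_solution,
                              SummedSolution)
from tests.conftest import make_random_problem

FAST = AnnealSchedule(n_iter=3000)


def toy_problem(costs, amounts, targets, status=None, spf=100.0, blm=0.0):
    """Hand-specified instance on a 1×n strip."""
    n = len(costs)
    amounts = np.atleast_2d(np.asarray(amounts, dtype=float))
    status = (np.asarray(status, dtype=np.int8) if status is not None
              else np.full(n, PUStatus.AVAILABLE, dtype=np.int8))
    pus = PlanningUnitSet(
        grid=GridSpec(1, n, 1.0), pu_index=np.arange(n).reshape(1, -1),
        area=np.ones(n), cost=np.asarray(costs, dtype=float), status=status,
        adjacency={(i, i + 1): 1.0 for i in range(n - 1)})
    fam = FeatureAmountMatrix(
        feature_ids=[f"f{i}" for i in range(amounts.shape[0])],
        kind=np.array(["species"] * amounts.shape[0]),
        amount=amounts, total_extent=amounts.sum(axis=1),
        protected_amount=amounts[:, status == PUStatus.LOCKED_IN].sum(axis=1))
    tt = pd.DataFrame({"feature_id": fam.feature_ids, "kind": fam.kind,
                       "target_km2": np.asarray(targets, dtype=float)})
    return SelectionProblem(pus=pus, amounts=fam, targets=tt,
                            spf=np.full(amounts.shape[0], spf), blm=blm)


class TestObjective:
    def test_all_targets_met_equals_cost_sum(self):
        p = toy_problem([1.0, 2.0, 4.0], [[3, 3, 3]], [2.0])
        sel = np.array([True, True, False])
        assert objective(p, sel) == pytest.approx(3.0)

    def test_empty_selection_is_pure_penalty(self):
        p = toy_problem([1.0, 1.0], [[1, 1]], [2.0], spf=7.0)
        sel = np.zeros(2, dtype=bool)
        # shortfall/target = 1; cost_scale = mean cost (1) * ceil(2/1) = 2
        assert objective(p, sel) == pytest.approx(7.0 * 2.0)

    def test_toy_hand_computed_sum(self):
        # 4 PUs, 2 features; select {0, 3}: cost 1+2, f0 short 50%, f1 met
        p = toy_problem([1.0, 5.0, 5.0, 2.0],
                        [[1, 1, 0, 0], [0, 0, 1, 2]],
                        [2.0, 2.0], spf=10.0)
        sel = np.array([True, False, False, True])
        cost_scale = p.cost_scale
        assert objective(p, sel) == pytest.approx(3.0 + 10.0 * cost_scale * 0.5)

    def test_boundary_term(self):
        p = toy_problem([1.0, 1.0, 1.0], [[1, 1, 1]], [0.5], blm=2.0)
        sel = np.array([True, False, False])  # one interior edge exposed
        assert objective(p, sel) == pytest.approx(1.0 + 2.0 * 1.0)

    def test_locked_out_selection_rejected(self):
        p = toy_problem([1.0, 1.0], [[1, 1]], [0.5],
                        status=[PUStatus.AVAILABLE, PUStatus.LOCKED_OUT])
        with pytest.raises(ValueError):
            objective(p, np.array([True, True]))


class TestAnneal:
    def test_single_covering_pu_is_selected(self):
        p = toy_problem([1.0, 1.0, 1.0], [[0, 5, 0]], [2.0])
        sol = anneal(p, FAST, seed=0)
        assert sol.selected[1] and sol.all_met

    def test_deterministic_for_fixed_seed(self):
        p = make_random_problem(3)
        a = anneal(p, FAST, seed=42)
        b = anneal(p, FAST, seed=42)
        assert np.array_equal(a.selected, b.selected)
        assert a.objective == b.objective

    def test_locked_out_never_selected(self):
        p = make_random_problem(1, n_pu=12, n_locked_out=4)
        for seed in range(100):
            sol = anneal(p, AnnealSchedule(n_iter=300), seed=seed)
            assert not (sol.selected & p.locked_out).any()

    def test_locked_in_always_selected(self):
        p = make_random_problem(2, n_pu=12, n_locked_in=3)
        sol = anneal(p, FAST, seed=7)
        assert (sol.selected[p.locked_in]).all()

    def test_reported_objective_equals_recomputation(self):
        for seed in range(5):
            p = make_random_problem(seed)
            sol = anneal(p, FAST, seed=seed)
            assert sol.objective == pytest.approx(objective(p, sol.selected))

    def test_infeasible_targets_flagged_not_raised(self):
        p = toy_problem([1.0, 1.0], [[1, 1]], [10.0])
        sol = anneal(p, FAST, seed=0)
        assert not sol.all_met

    def test_beats_or_matches_greedy_baseline(self):
        for seed in range(10):
            p = make_random_problem(seed + 100)
            sa = anneal(p, AnnealSchedule(n_iter=30_000), seed=seed)
            greedy = greedy_add_baseline(p)
            assert sa.objective <= greedy.objective + 1e-9

    def test_large_spf_meets_feasible_targets(self):
        for seed in range(10):
            p = make_random_problem(seed + 50, spf=1e6)
            sol = anneal(p, AnnealSchedule(n_iter=10_000), seed=seed)
            assert sol.all_met


class TestBruteForce:
    def test_no_available_returns_locked_in(self):
        p = make_random_problem(4, n_pu=6, n_locked_in=6)
        sol = brute_force_optimum(p)
        assert np.array_equal(sol.selected, p.locked_in)

    def test_three_pu_known_best_subset(self):
        # f0 needs 2 units; PU1 alone covers it at cost 2 < PU0+PU2 (1.5+1.5)
        p = toy_problem([1.5, 2.0, 1.5], [[1, 2, 1]], [2.0], spf=1000.0)
        sol = brute_force_optimum(p)
        assert list(sol.selected) == [False, True, False]

    def test_agrees_with_own_objective(self):
        p = make_random_problem(9)
        sol = brute_force_optimum(p)
        assert sol.objective == pytest.approx(objective(p, sol.selected))

    def test_too_many_pus_errors(self):
        p = make_random_problem(0, n_pu=25)
        with pytest.raises(ValueError):
            brute_force_optimum(p)

    def test_respects_locks(self):
        p = make_random_problem(11, n_pu=10, n_locked_in=2, n_locked_out=3)
        sol = brute_force_optimum(p)
        assert sol.selected[p.locked_in].all()
        assert not sol.selected[p.locked_out].any()


class TestSummedSolution:
    def test_single_rep_frequencies_binary(self):
        p = make_random_problem(5)
        ss = summed_solution(p, n_reps=1, base_seed=0, schedule=FAST)
        assert set(np.unique(ss.frequency)) <= {0, 1}

    def test_lock_invariants(self):
        p = make_random_problem(6, n_pu=12, n_locked_in=2, n_locked_out=2)
        ss = summed_solution(p, n_reps=10, base_seed=3, schedule=FAST)
        assert (ss.frequency[p.locked_in] == 10).all()
        assert (ss.frequency[p.locked_out] == 0).all()

    def test_dominant_pu_selected_in_nearly_all_reps(self):
        # one PU covers the only feature cheaply; every replicate needs it
        p = toy_problem([10.0, 0.5, 10.0], [[1, 5, 1]], [4.0], spf=1000.0)
        ss = summed_solution(p, n_reps=100, base_seed=0,
                             schedule=AnnealSchedule(n_iter=1000))
        assert ss.frequency[1] >= 95

    def test_best_solution_tracked(self):
        p = make_random_problem(8)
        ss = summed_solution(p, n_reps=5, base_seed=0, schedule=FAST)
        objs = [anneal(p, FAST, seed=k).objective for k in range(5)]
        assert ss.best.objective == pytest.approx(min(objs))


class TestPriorityAreas:
    def test_inclusive_threshold_boundary(self):
        ss = SummedSolution(frequency=np.array([75, 74, 100, 0]), n_reps=100)
        m = priority_areas(ss)
        assert list(m) == [True, False, True, False]

    def test_zero_threshold_selects_everything(self):
        ss = SummedSolution(frequency=np.array([0, 10]), n_reps=100)
        assert priority_areas(ss, threshold=0).all()
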