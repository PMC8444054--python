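"""Scenario logic: enumeration, aggregation, optima, regional benefit."""

import datetime as dt
import itertools
from math import comb

import numpy as np
import pytest

import regionsim as rs
from regionsim.errors import ArgumentError
from regionsim.interventions import InterventionSet
from regionsim.params import CatchmentParameters
from regionsim.scenarios import (
    CatchmentSweep,
    ForecastWindow,
    ScenarioResult,
    enumerate_combinations,
    optimal_state_combination,
    regional_planning_benefit,
    run_baseline,
    run_scenario,
    state_level_effect,
    suboptimality_count,
    sweep_catchment,
)


class TestEnumeration:
    def test_four_of_thirteen_gives_715(self, catalogue):
        assert len(enumerate_combinations(catalogue, 4)) == 715

    def test_five_of_thirteen_gives_1287(self, catalogue):
        assert len(enumerate_combinations(catalogue, 5)) == 1287

    def test_zero_subset_is_the_empty_set(self, catalogue):
        sets = enumerate_combinations(catalogue, 0)
        assert sets == [InterventionSet()]

    def test_lexicographic_order_and_uniqueness(self, catalogue):
        sets = enumerate_combinations(catalogue, 2)
        members = [s.members for s in sets]
        assert members == sorted(members)
        assert len(set(members)) == len(members) == comb(13, 2)

    def test_out_of_range_k_rejected(self, catalogue):
        with pytest.raises(ArgumentError):
            enumerate_combinations(catalogue, 14)


class TestAggregation:
    def _mk(self, name, reduction, members=("a", "b")):
        return ScenarioResult(name, InterventionSet(members), 100.0, reduction, reduction)

    def test_sum_of_reductions(self):
        results = [self._mk("c1", 10.0), self._mk("c2", 20.0), self._mk("c3", 30.0)]
        assert state_level_effect(results) == 60.0

    def test_zero_everywhere(self):
        assert state_level_effect([self._mk("c", 0.0)] * 3) == 0.0

    def test_order_invariant(self):
        results = [self._mk("c1", 1.25), self._mk("c2", -0.5), self._mk("c3", 4.0)]
        assert state_level_effect(results) == state_level_effect(results[::-1])

    def test_mixed_sets_rejected(self):
        bad = [self._mk("c1", 1.0, ("a", "b")), self._mk("c2", 1.0, ("a", "c"))]
        with pytest.raises(ArgumentError, match="mix"):
            state_level_effect(bad)


class TestBaselineAndScenario:
    def test_baseline_reduction_is_exactly_zero(self, grid20, window):
        r = run_baseline(CatchmentParameters(), grid20, window)
        assert r.reduction == 0.0 and r.pct_reduction == 0.0
        assert len(r.interventions) == 0

    def test_baseline_equals_window_difference_of_cumulative_stock(self, grid20, window):
        p = CatchmentParameters()
        r = run_baseline(p, grid20, window)
        traj = rs.simulate(p, grid20)
        s = traj.series("cum_suicides")
        ws, we = window.weeks(grid20)
        expected = s[grid20.step_of_week(we)] - s[grid20.step_of_week(ws)]
        assert r.cumulative_suicides == pytest.approx(expected, abs=0)

    def test_empty_set_scenario_identical_to_baseline(self, grid20, window):
        p = CatchmentParameters()
        base = run_baseline(p, grid20, window)
        r = run_scenario(p, InterventionSet(), grid20, window)
        assert r.cumulative_suicides == base.cumulative_suicides
        assert r.reduction == 0.0

    def test_window_outside_grid_rejected(self):
        grid = rs.build_time_grid(dt.date(2011, 1, 1), 5, 8)
        with pytest.raises(ArgumentError, match="horizon"):
            run_baseline(CatchmentParameters(), grid, ForecastWindow())

    def test_batched_sweep_matches_individual_runs(self, grid20, window, catalogue):
        p = CatchmentParameters()
        sets = [
            InterventionSet(["post_attempt_care"]),
            InterventionSet(["awareness_campaign", "safety_planning"]),
        ]
        sweep = sweep_catchment(p, sets, grid20, window, catalogue)
        base = run_baseline(p, grid20, window)
        for j, s in enumerate(sets):
            r = run_scenario(p, s, grid20, window, catalogue, base.cumulative_suicides)
            assert sweep.reduction[j] == pytest.approx(r.reduction, abs=1e-6)


@pytest.fixture(scope="module")
def toy(catalogue):
    """Two small catchments and a 5-intervention toy catalogue."""
    ids = [
        "post_attempt_care",
        "safety_planning",
        "care_coordination",
        "awareness_campaign",
        "social_connectedness",
    ]
    cat = [s for s in catalogue if s.id in ids]
    slack = CatchmentParameters(name="slack")
    slack.initial_population = 300_000.0
    slack.gp_capacity = 900.0
    slack.specialist_capacity = 250.0
    slack.cmhc_capacity = 90.0
    slack.inpatient_capacity = 40.0
    starved = CatchmentParameters(name="starved")
    starved.initial_population = 300_000.0
    starved.ed_presentation_rate = 2 * slack.ed_presentation_rate
    starved.gp_capacity = 400.0
    starved.specialist_capacity = 100.0
    starved.cmhc_capacity = 40.0
    starved.inpatient_capacity = 25.0
    grid = rs.build_time_grid(dt.date(2011, 1, 1), 20, 4)
    return cat, [slack, starved], grid


class TestOptimalSearch:
    def test_exhaustive_optimum_matches_brute_force(self, toy, window):
        """Independent brute force: per-set scalar runs over all C(5,2) subsets."""
        cat, catchments, grid = toy
        best, best_red, sweeps = optimal_state_combination(catchments, 2, grid, window, cat)

        totals = {}
        ids = sorted(s.id for s in cat)
        for combo in itertools.combinations(ids, 2):
            total = 0.0
            for p in catchments:
                base = run_baseline(p, grid, window)
                r = run_scenario(p, InterventionSet(combo), grid, window, cat,
                                 base.cumulative_suicides)
                total += r.reduction
            totals[combo] = total
        brute_best = max(sorted(totals), key=lambda c: round(totals[c], 6))
        assert best.members == brute_best
        assert best_red == pytest.approx(totals[brute_best], abs=1e-6)
        # returned reduction dominates every enumerated alternative
        assert all(round(best_red, 6) >= round(v, 6) for v in totals.values())

    def test_state_optimum_can_differ_from_both_catchment_optima(self, toy, window):
        cat, catchments, grid = toy
        best, _, sweeps = optimal_state_combination(catchments, 2, grid, window, cat)
        own = [sw.sets[sw.best_index()] for sw in sweeps]
        # the two catchments disagree about the best pair
        assert own[0] != own[1]

    def test_single_catchment_state_optimum_is_its_own(self, toy, window):
        cat, catchments, grid = toy
        best, red, sweeps = optimal_state_combination(catchments[:1], 2, grid, window, cat)
        assert best == sweeps[0].sets[sweeps[0].best_index()]

    def test_regional_benefit_matches_brute_force_difference(self, toy, window):
        cat, catchments, grid = toy
        best, _, sweeps = optimal_state_combination(catchments, 2, grid, window, cat)
        for sw in sweeps:
            own, extra, pct = regional_planning_benefit(sw, best)
            j_state = sw.sets.index(best)
            expected = max(sw.reduction) - sw.reduction[j_state]
            assert extra == pytest.approx(expected, abs=1e-5)
            assert extra >= 0.0

    def test_identical_interventions_give_zero_suboptimality(self, toy, window):
        cat, catchments, grid = toy
        # catalogue of clones: every set performs identically
        from regionsim.interventions import Effect, InterventionSpec

        clones = [
            InterventionSpec(f"clone_{i}", f"clone {i}",
                             (Effect("attempt_rate_postdischarge", "multiply", 0.7),))
            for i in range(4)
        ]
        sweep = sweep_catchment(
            catchments[0], enumerate_combinations(clones, 2), grid, window, clones
        )
        count, share = suboptimality_count(sweep, sweep.sets[0])
        assert count == 0 and share == 0.0


class TestSuboptimalityArithmetic:
    def test_printed_share_for_666_of_715(self):
        sweep = CatchmentSweep(
            "c", [InterventionSet([f"i{j}"]) for j in range(715)], 100.0,
            np.zeros(715), np.concatenate([np.zeros(49), -np.ones(666)]),
        )
        count, share = suboptimality_count(sweep, sweep.sets[0])
        assert count == 666
        assert round(share, 1) == 93.1

    def test_share_for_1_of_1287(self):
        red = np.zeros(1287)
        red[-1] = -1.0
        sweep = CatchmentSweep(
            "c", [InterventionSet([f"i{j}"]) for j in range(1287)], 100.0,
            np.zeros(1287), red,
        )
        count, share = suboptimality_count(sweep, sweep.sets[0])
        assert count == 1
        assert round(share, 2) == 0.08

    def test_count_excludes_the_state_set_itself(self):
        sweep = CatchmentSweep(
            "c", [InterventionSet([f"i{j}"]) for j in range(10)], 100.0,
            np.zeros(10), np.arange(10, dtype=float),
        )
        count, _ = suboptimality_count(sweep, sweep.sets[0])
        assert count <= 9
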