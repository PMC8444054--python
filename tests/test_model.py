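"""Core model: sector flows, closure, queueing, yearly metrics."""

import datetime as dt

import numpy as np
import pytest

import regionsim as rs
from regionsim.engine import build_time_grid
from regionsim.errors import ArgumentError
from regionsim.model import (
    STOCKS,
    initial_state,
    simulate,
    waiting_time,
    yearly_output_metrics,
)
from regionsim.engine import TimeGrid, Trajectory
from regionsim.params import CatchmentParameters


def quiet_params(**overrides) -> CatchmentParameters:
    """A parameter set with selected sectors switched off for closed-form checks."""
    p = CatchmentParameters()
    p.birth_rate = p.migration_rate = p.background_mortality = 0.0
    p.attempt_rate_distressed_untreated = 0.0
    p.attempt_rate_in_care = 0.0
    p.attempt_rate_postdischarge = 0.0
    for k, v in overrides.items():
        setattr(p, k, v)
    p.validate()
    return p


class TestWaitingTime:
    def test_queue_over_capacity(self):
        assert waiting_time(100.0, 50.0) == pytest.approx(2.0)

    def test_empty_queue(self):
        assert waiting_time(0.0, 50.0) == 0.0

    def test_doubling_capacity_halves_wait(self):
        assert waiting_time(80.0, 40.0) == pytest.approx(2 * waiting_time(80.0, 80.0))

    def test_zero_capacity_returns_cap_not_infinity(self):
        assert waiting_time(10.0, 0.0, cap=52.0) == 52.0


class TestPopulationSector:
    def test_all_demographic_rates_zero_gives_constant_population(self):
        p = quiet_params()
        grid = build_time_grid(dt.date(2011, 1, 1), 1, 8)
        traj = simulate(p, grid)
        pop = traj.aux("population")
        assert np.max(np.abs(pop - pop[0])) / pop[0] < 1e-12

    def test_net_demographic_inflow_arithmetic(self):
        # (birth + migration - mortality) * population net inflow per week
        p = quiet_params(birth_rate=2e-4, migration_rate=1e-4, background_mortality=1e-4)
        from regionsim.model import CatchmentModel

        model = CatchmentModel(p)
        rates = model.rates_array(initial_state(p).values, 0.0)
        net = rates[:11].sum()
        assert net == pytest.approx((2e-4 + 1e-4 - 1e-4) * 1e6, rel=1e-9)

    def test_population_matches_exponential_closed_form(self):
        p = quiet_params(birth_rate=3e-4, migration_rate=1e-4, background_mortality=2e-4)
        grid = build_time_grid(dt.date(2011, 1, 1), 10, 8)
        traj = simulate(p, grid)
        pop = traj.aux("population")
        t = grid.times_weeks()
        exact = pop[0] * np.exp((3e-4 + 1e-4 - 2e-4) * t)
        assert np.max(np.abs(pop - exact) / exact) < 1e-3  # Euler tolerance


class TestDistressSector:
    def test_two_state_chain_reaches_analytic_equilibrium(self):
        o, r = 0.004, 0.012
        p = quiet_params(
            distress_onset_rate=o,
            distress_recovery_untreated=r,
            help_seeking_rate=0.0,
        )
        grid = build_time_grid(dt.date(2011, 1, 1), 10, 8)
        prev = simulate(p, grid).aux("distress_prevalence")
        assert prev[-1] == pytest.approx(o / (o + r), rel=1e-3)

    def test_zero_onset_prevalence_decays_to_zero(self):
        p = quiet_params(distress_onset_rate=0.0, help_seeking_rate=0.0)
        grid = build_time_grid(dt.date(2011, 1, 1), 10, 8)
        prev = simulate(p, grid).aux("distress_prevalence")
        assert prev[-1] < 1e-3

    def test_prevalence_always_a_proportion(self):
        p = CatchmentParameters()
        grid = build_time_grid(dt.date(2011, 1, 1), 5, 8)
        prev = simulate(p, grid).aux("distress_prevalence")
        assert np.all((prev >= 0) & (prev <= 1))


class TestServicesSector:
    def test_zero_help_seeking_leaves_services_empty(self):
        p = quiet_params(help_seeking_rate=0.0)
        grid = build_time_grid(dt.date(2011, 1, 1), 2, 8)
        traj = simulate(p, grid)
        for stock in STOCKS[2:11]:
            assert np.all(traj.series(stock) == 0.0), stock

    def test_slack_capacity_keeps_queues_near_zero(self):
        p = CatchmentParameters()
        p.gp_capacity *= 3
        p.specialist_capacity *= 3
        grid = build_time_grid(dt.date(2011, 1, 1), 5, 8)
        traj = simulate(p, grid)
        w = traj.aux("waiting_time_gp")
        assert w[-1] < 0.5  # well under the intake floor

    def test_starved_capacity_grows_queue_and_disengagement(self):
        p = CatchmentParameters()
        p.gp_capacity *= 0.4  # roughly half of steady inflow
        grid = build_time_grid(dt.date(2011, 1, 1), 5, 8)
        traj = simulate(p, grid)
        assert traj.aux("waiting_time_gp")[-1] > 2.0
        diseng = np.diff(traj.series("cum_disengagements"))
        assert diseng[-1] > 0

    @pytest.mark.parametrize("path", ["gp_capacity", "specialist_capacity", "cmhc_capacity"])
    def test_capacity_increase_weakly_reduces_suicides(self, path, remote_catchment):
        grid = build_time_grid(dt.date(2011, 1, 1), 10, 8)
        base = simulate(remote_catchment, grid).series("cum_suicides")[-1]
        boosted = remote_catchment.with_path(path, 1.3 * remote_catchment.get_path(path))
        up = simulate(boosted, grid).series("cum_suicides")[-1]
        assert up <= base + 1e-9


class TestSuicidalBehaviourSector:
    def test_no_attempts_means_no_suicides(self):
        p = quiet_params()
        grid = build_time_grid(dt.date(2011, 1, 1), 2, 8)
        traj = simulate(p, grid)
        assert np.all(traj.series("cum_suicides") == 0.0)

    def test_constant_hazard_closed_form(self):
        # one risk group, hazard r, fatality f, horizon T: suicides ~ N*r*f*T
        p = quiet_params(
            help_seeking_rate=0.0,
            distress_onset_rate=0.0,
            distress_recovery_untreated=0.0,
            hospitalisation_fraction_of_attempts=0.0,
            ed_presentation_rate=0.0,
        )
        p.attempt_rate_distressed_untreated = 3e-4
        p.attempt_rate_in_care = 1e-4
        p.case_fatality = 0.05
        grid = build_time_grid(dt.date(2011, 1, 1), 1, 8)
        traj = simulate(p, grid)
        n0 = p.initial_population * p.initial_distress_prevalence
        expected = n0 * 3e-4 * 0.05 * 52
        got = traj.series("cum_suicides")[-1]
        assert got == pytest.approx(expected, rel=5e-3)

    def test_care_is_protective(self):
        # moving distressed persons into community care lowers cumulative suicides
        p = CatchmentParameters()
        grid = build_time_grid(dt.date(2011, 1, 1), 2, 8)
        s_all_untreated = initial_state(p)
        s_half_in_care = initial_state(p)
        i_dnc = STOCKS.index("distressed_not_in_care")
        i_cm = STOCKS.index("in_cmhc")
        moved = s_half_in_care.values[i_dnc] / 2
        s_half_in_care.values[i_dnc] -= moved
        s_half_in_care.values[i_cm] += moved
        a = simulate(p, grid, state0=s_all_untreated).series("cum_suicides")[-1]
        b = simulate(p, grid, state0=s_half_in_care).series("cum_suicides")[-1]
        assert b < a


class TestYearlyMetrics:
    def _flat_trajectory(self, suicide_per_week=2.0, years=1, spw=1):
        grid = build_time_grid(dt.date(2011, 1, 1), years, spw)
        t = grid.times_weeks()
        states = np.zeros((grid.n_steps + 1, len(STOCKS)))
        states[:, STOCKS.index("cum_suicides")] = suicide_per_week * t
        return Trajectory(grid, STOCKS, states, {})

    def test_constant_flow_gives_104_per_model_year(self):
        m = yearly_output_metrics(self._flat_trajectory(2.0))
        assert m["suicides"][0] == pytest.approx(104.0)

    def test_yearly_sums_telescope_to_cumulative_difference(self):
        p = CatchmentParameters()
        grid = build_time_grid(dt.date(2011, 1, 1), 5, 8)
        traj = simulate(p, grid)
        m = yearly_output_metrics(traj)
        cum = traj.series("cum_suicides")
        assert m["suicides"].sum() == pytest.approx(cum[-1] - cum[0], abs=1e-9)

    def test_all_zero_model_gives_zero_metrics(self):
        m = yearly_output_metrics(self._flat_trajectory(0.0))
        for name, series in m.items():
            assert np.all(series == 0.0), name

    def test_all_metrics_nonnegative_on_default_run(self):
        p = CatchmentParameters()
        grid = build_time_grid(dt.date(2011, 1, 1), 3, 8)
        m = yearly_output_metrics(simulate(p, grid))
        for name, series in m.items():
            assert np.all(series >= 0.0), name

    def test_sub_year_trajectory_rejected(self):
        grid = TimeGrid(dt.date(2011, 1, 1), 10, 1)
        states = np.zeros((11, len(STOCKS)))
        with pytest.raises(ArgumentError):
            yearly_output_metrics(Trajectory(grid, STOCKS, states, {}))

    def test_partial_final_year_excluded_with_warning(self):
        grid = TimeGrid(dt.date(2011, 1, 1), 78, 1)  # 1.5 model years
        t = grid.times_weeks()
        states = np.zeros((grid.n_steps + 1, len(STOCKS)))
        states[:, STOCKS.index("cum_suicides")] = 2.0 * t
        with pytest.warns(UserWarning, match="partial"):
            m = yearly_output_metrics(Trajectory(grid, STOCKS, states, {}))
        assert len(m["suicides"]) == 1


def test_population_closure_on_default_catchment():
    """Living-person stocks must track the demographically implied population."""
    p = CatchmentParameters()
    grid = build_time_grid(dt.date(2011, 1, 1), 5, 8)
    traj = simulate(p, grid)
    person = traj.states[:, :11].sum(axis=1)
    cs = traj.series("cum_suicides")
    net = p.birth_rate + p.migration_rate - p.background_mortality
    implied = np.empty_like(person)
    implied[0] = person[0]
    dt_w = grid.dt_weeks
    for k in range(len(person) - 1):
        implied[k + 1] = implied[k] + dt_w * net * implied[k] - (cs[k + 1] - cs[k])
    assert np.max(np.abs(person - implied) / implied) < 1e-6
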