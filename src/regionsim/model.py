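"""Core stock-and-flow model of one catchment.

Four interconnected sectors over a declared stock set:

* **population** — births, net migration and background mortality acting on
  every living-person stock;
* **psychological distress** — onset (low → distressed) and recovery
  (distressed → low), with faster recovery while in care and slowed natural
  recovery while stuck in a queue;
* **mental health services** — help seeking into a GP-led pathway (with a
  direct-to-online fraction), capacity-constrained GP and specialist
  intakes, referral of completed GP episodes to specialist / community /
  inpatient / online channels, post-discharge elevated-risk residence,
  waiting-time-driven disengagement plus dissatisfaction-driven
  disengagement, and exponentially growing service capacities;
* **suicidal behaviour** — group-specific attempt hazards (untreated and
  queued and disengaged share one rate, in-care a lower rate,
  post-discharge an elevated rate), a case-fatality fraction converting
  attempts to suicides (removed from the population), and a
  hospitalisation fraction routing surviving attempters into inpatient
  care.

The exact equations are a reconstruction faithful to the sector structure
described for the published regional models; every functional form used
here is documented in ``docs/methods.md``.

All person stocks are in persons, event stocks are cumulative counts,
capacity stocks are in service units (intakes/week; beds for inpatient).
Rates are per week.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np

from .engine import (
    WEEKS_PER_YEAR,
    ModelState,
    TimeGrid,
    Trajectory,
    integrate,
)
from .errors import ArgumentError
from .interventions import InterventionSet, ParamSchedule, catalogue_by_id, default_catalogue
from .params import CatchmentParameters

__all__ = [
    "STOCKS",
    "PERSON_STOCKS",
    "EVENT_STOCKS",
    "CatchmentModel",
    "initial_state",
    "simulate",
    "waiting_time",
    "yearly_output_metrics",
]

#: Fixed stock declaration order (reproducible state vectors).
STOCKS = (
    "low_distress",
    "distressed_not_in_care",
    "waiting_gp",
    "in_gp_care",
    "waiting_specialist",
    "in_specialist_care",
    "in_cmhc",
    "in_inpatient",
    "in_online",
    "post_discharge",
    "disengaged",
    "cum_suicides",
    "cum_selfharm_hospitalisations",
    "cum_ed_presentations",
    "cum_gp_consultations",
    "cum_specialist_consultations",
    "cum_cmhc_contacts",
    "cum_inpatient_admissions",
    "cum_disengagements",
    "cap_gp",
    "cap_specialist",
    "cap_cmhc",
    "cap_inpatient",
)

PERSON_STOCKS = STOCKS[:11]
EVENT_STOCKS = STOCKS[11:19]
CAPACITY_STOCKS = STOCKS[19:]

_IDX = {name: i for i, name in enumerate(STOCKS)}


def waiting_time(queue, service_capacity, cap: float = 52.0):
    """Expected wait (weeks) = queue / capacity, capped at ``cap``.

    A zero capacity returns the cap rather than infinity.
    """
    return np.minimum(queue / (service_capacity + 1e-12), cap)


def _mn(a, b):
    if type(a) is float and type(b) is float:
        return a if a < b else b
    return np.minimum(a, b)


def _log1p(x):
    if type(x) is float:
        return math.log1p(x)
    return np.log1p(x)


class CatchmentModel:
    """Vector flow evaluator for one catchment (optionally batched).

    Implements the engine's fast-path interface: ``rates_array(values, t)``
    and ``aux_array(values, t)``.  ``values`` is the state vector in
    :data:`STOCKS` order, shape ``(n_stocks,)`` or ``(n_stocks, batch)``.
    A :class:`~regionsim.interventions.ParamSchedule` makes selected
    parameters time-dependent (and, with array magnitudes, batch-varying).
    """

    names = STOCKS

    def __init__(
        self,
        params: CatchmentParameters,
        schedule: ParamSchedule | None = None,
    ):
        params.validate()
        self.params = params
        self.schedule = schedule
        self._base = self._flatten(params)

    @staticmethod
    def _flatten(p: CatchmentParameters) -> dict[str, float]:
        d: dict[str, float] = {}
        for name in (
            "birth_rate",
            "migration_rate",
            "background_mortality",
            "distress_onset_rate",
            "distress_recovery_untreated",
            "distress_recovery_in_care",
            "waiting_recovery_factor",
            "disengaged_recovery_factor",
            "help_seeking_rate",
            "reengagement_factor",
            "direct_online_fraction",
            "ed_presentation_rate",
            "gp_care_duration",
            "specialist_care_duration",
            "cmhc_care_duration",
            "online_care_duration",
            "inpatient_los",
            "min_intake_wait",
            "waiting_tolerance",
            "disengagement_max_rate",
            "dissatisfaction_rate",
            "max_waiting_time",
            "attempt_rate_distressed_untreated",
            "attempt_rate_in_care",
            "attempt_rate_postdischarge",
            "hospitalisation_fraction_of_attempts",
            "case_fatality",
            "postdischarge_window",
            "postdischarge_recovery_fraction",
            "safety_planning_strength",
            "safety_planning_reach_scale",
        ):
            d[name] = float(getattr(p, name))
        for k, v in p.capacity_growth.items():
            d[f"capacity_growth.{k}"] = float(v)
        for k, v in p.referral_fractions.items():
            d[f"referral_fractions.{k}"] = float(v)
        return d

    def _effective(self, t: float) -> dict[str, object]:
        if self.schedule is None:
            return self._base
        ov = self.schedule.overrides(t)
        if not ov:
            return self._base
        eff = dict(self._base)
        eff.update(ov)
        return eff

    # -- engine interface -------------------------------------------------
    def rates_array(self, values: np.ndarray, t: float) -> np.ndarray:
        P = self._effective(t)
        if values.ndim == 1:
            (low, dnc, wgp, igp, wsp, isp, cm, inp, onl, pd, dis,
             _cs, _ch, _ce, _cg, _cp, _cc, _ci, _cd,
             cap_gp, cap_sp, cap_cm, cap_inp) = values.tolist()
        else:
            (low, dnc, wgp, igp, wsp, isp, cm, inp, onl, pd, dis) = values[:11]
            (cap_gp, cap_sp, cap_cm, cap_inp) = values[19:]

        pop = low + dnc + wgp + igp + wsp + isp + cm + inp + onl + pd + dis
        distressed = pop - low

        # population sector -------------------------------------------------
        births = P["birth_rate"] * pop
        net_demo = P["migration_rate"] - P["background_mortality"]

        # distress sector ---------------------------------------------------
        onset = P["distress_onset_rate"] * low
        rec_u = P["distress_recovery_untreated"]
        rec_c = P["distress_recovery_in_care"]
        rec_w = rec_u * P["waiting_recovery_factor"]
        rec_dnc = rec_u * dnc
        rec_dis = rec_u * P["disengaged_recovery_factor"] * dis
        rec_wgp = rec_w * wgp
        rec_wsp = rec_w * wsp
        rec_igp = rec_c * igp
        rec_isp = rec_c * isp
        rec_cm = rec_c * cm
        rec_onl = rec_c * onl

        # services sector ---------------------------------------------------
        hs = P["help_seeking_rate"]
        donl = P["direct_online_fraction"]
        seek = hs * dnc
        seek_onl = donl * seek
        seek_gp = seek - seek_onl
        reseek = hs * P["reengagement_factor"] * dis

        miw = P["min_intake_wait"]
        intake_gp = _mn(wgp / miw, cap_gp)
        intake_sp = _mn(wsp / miw, cap_sp)

        comp_gp = igp / P["gp_care_duration"]
        ref_sp = P["referral_fractions.specialist"] * comp_gp
        ref_cm = P["referral_fractions.cmhc"] * comp_gp
        ref_inp = P["referral_fractions.inpatient"] * comp_gp
        ref_onl = P["referral_fractions.online"] * comp_gp
        ref_dnc = P["referral_fractions.discharge"] * comp_gp

        admit_cm = _mn(ref_cm, cap_cm)
        cm_refused = ref_cm - admit_cm

        comp_sp = isp / P["specialist_care_duration"]
        comp_cm = cm / P["cmhc_care_duration"]
        comp_onl = onl / P["online_care_duration"]

        # suicidal behaviour sector ----------------------------------------
        reach = _mn(1.0, P["ed_presentation_rate"] * P["safety_planning_reach_scale"])
        sp_mult = 1.0 - P["safety_planning_strength"] * reach
        att_u = P["attempt_rate_distressed_untreated"] * sp_mult
        att_c = P["attempt_rate_in_care"]
        a_dnc = att_u * dnc
        a_dis = att_u * dis
        a_wgp = att_u * wgp
        a_wsp = att_u * wsp
        a_igp = att_c * igp
        a_isp = att_c * isp
        a_cm = att_c * cm
        a_inp = att_c * inp
        a_onl = att_c * onl
        a_pd = P["attempt_rate_postdischarge"] * pd
        attempts = (
            a_dnc + a_dis + a_wgp + a_wsp + a_igp + a_isp
            + a_cm + a_inp + a_onl + a_pd
        )
        f = P["case_fatality"]
        hf = P["hospitalisation_fraction_of_attempts"]
        suicides = f * attempts
        selfharm_hosp = hf * attempts
        # surviving hospitalised attempters are routed to inpatient care
        hsurv = hf * (1.0 - f)
        h_dnc = hsurv * a_dnc
        h_dis = hsurv * a_dis
        h_wgp = hsurv * a_wgp
        h_wsp = hsurv * a_wsp
        h_igp = hsurv * a_igp
        h_isp = hsurv * a_isp
        h_cm = hsurv * a_cm
        h_onl = hsurv * a_onl
        h_pd = hsurv * a_pd
        hosp_demand = (
            h_dnc + h_dis + h_wgp + h_wsp + h_igp + h_isp + h_cm + h_onl + h_pd
        )

        inp_throughput = cap_inp / P["inpatient_los"]
        inp_demand = ref_inp + hosp_demand
        admit_inp = _mn(inp_demand, inp_throughput)
        frac_adm = admit_inp / (inp_demand + 1e-30)
        inp_refused_ref = (1.0 - frac_adm) * ref_inp
        disch_inp = inp / P["inpatient_los"]

        pd_exit = pd / P["postdischarge_window"]
        pr = P["postdischarge_recovery_fraction"]

        # disengagement -----------------------------------------------------
        wcap = P["max_waiting_time"]
        w_gp = waiting_time(wgp, cap_gp, wcap)
        w_sp = waiting_time(wsp, cap_sp, wcap)
        dmax = P["disengagement_max_rate"]
        tol = P["waiting_tolerance"]
        d_wgp = dmax * w_gp / (w_gp + tol) * wgp
        d_wsp = dmax * w_sp / (w_sp + tol) * wsp
        dsr = P["dissatisfaction_rate"]
        d_igp = dsr * igp
        d_isp = dsr * isp
        d_cm = dsr * cm
        d_onl = dsr * onl
        diseng = d_wgp + d_wsp + d_igp + d_isp + d_cm + d_onl

        # capacity growth (continuous exponential at the yearly rate) -------
        g_gp = _log1p(P["capacity_growth.gp"]) / WEEKS_PER_YEAR * cap_gp
        g_sp = _log1p(P["capacity_growth.specialist"]) / WEEKS_PER_YEAR * cap_sp
        g_cm = _log1p(P["capacity_growth.cmhc"]) / WEEKS_PER_YEAR * cap_cm
        g_inp = _log1p(P["capacity_growth.inpatient"]) / WEEKS_PER_YEAR * cap_inp

        out = np.empty_like(values)
        out[0] = (  # low_distress
            births + net_demo * low - onset
            + rec_dnc + rec_dis + rec_wgp + rec_wsp
            + rec_igp + rec_isp + rec_cm + rec_onl
            + pr * pd_exit
        )
        out[1] = (  # distressed_not_in_care
            net_demo * dnc + onset - rec_dnc - seek
            + ref_dnc + cm_refused + inp_refused_ref
            + comp_sp + comp_cm + comp_onl
            + (1.0 - pr) * pd_exit
            - f * a_dnc - frac_adm * h_dnc
        )
        out[2] = (  # waiting_gp
            net_demo * wgp + seek_gp + reseek - intake_gp - rec_wgp
            - d_wgp - f * a_wgp - frac_adm * h_wgp
        )
        out[3] = (  # in_gp_care
            net_demo * igp + intake_gp - comp_gp - rec_igp - d_igp
            - f * a_igp - frac_adm * h_igp
        )
        out[4] = (  # waiting_specialist
            net_demo * wsp + ref_sp - intake_sp - rec_wsp - d_wsp
            - f * a_wsp - frac_adm * h_wsp
        )
        out[5] = (  # in_specialist_care
            net_demo * isp + intake_sp - comp_sp - rec_isp - d_isp
            - f * a_isp - frac_adm * h_isp
        )
        out[6] = (  # in_cmhc
            net_demo * cm + admit_cm - comp_cm - rec_cm - d_cm
            - f * a_cm - frac_adm * h_cm
        )
        out[7] = (  # in_inpatient
            net_demo * inp + admit_inp - disch_inp - f * a_inp
        )
        out[8] = (  # in_online
            net_demo * onl + seek_onl + ref_onl - comp_onl - rec_onl - d_onl
            - f * a_onl - frac_adm * h_onl
        )
        out[9] = (  # post_discharge
            net_demo * pd + disch_inp - pd_exit - f * a_pd - frac_adm * h_pd
        )
        out[10] = (  # disengaged
            net_demo * dis + diseng - reseek - rec_dis
            - f * a_dis - frac_adm * h_dis
        )
        out[11] = suicides
        out[12] = selfharm_hosp
        out[13] = P["ed_presentation_rate"] * distressed
        out[14] = igp + intake_gp
        out[15] = isp + intake_sp
        out[16] = cm
        out[17] = admit_inp
        out[18] = diseng
        out[19] = g_gp
        out[20] = g_sp
        out[21] = g_cm
        out[22] = g_inp
        return out

    def aux_array(self, values: np.ndarray, t: float) -> dict:
        P = self._effective(t)
        person = values[:11]
        pop = person.sum(axis=0)
        distressed = pop - values[0]
        w_gp = waiting_time(values[2], values[19], P["max_waiting_time"])
        w_sp = waiting_time(values[4], values[20], P["max_waiting_time"])
        return {
            "population": pop,
            "distress_prevalence": distressed / pop,
            "waiting_time_gp": w_gp,
            "waiting_time_specialist": w_sp,
        }

    # -- convenience ------------------------------------------------------
    def flows(self, state: ModelState, t: float) -> dict[str, float]:
        """Mapping-style view of the net rates (contract interface)."""
        rates = self.rates_array(np.asarray(state.values, dtype=float), t)
        return dict(zip(STOCKS, rates))


def initial_state(p: CatchmentParameters, batch: int | None = None) -> ModelState:
    """Initial stocks on 1 January of the simulation start year.

    All initially distressed residents start outside care; service stocks
    fill during the first months of the run (a short, documented
    transient).  Capacity stocks start at their configured levels.
    """
    v = np.zeros(len(STOCKS))
    v[_IDX["low_distress"]] = p.initial_population * (1 - p.initial_distress_prevalence)
    v[_IDX["distressed_not_in_care"]] = p.initial_population * p.initial_distress_prevalence
    v[_IDX["cap_gp"]] = p.gp_capacity
    v[_IDX["cap_specialist"]] = p.specialist_capacity
    v[_IDX["cap_cmhc"]] = p.cmhc_capacity
    v[_IDX["cap_inpatient"]] = p.inpatient_capacity
    if batch is not None:
        v = np.repeat(v[:, None], batch, axis=1)
    return ModelState(STOCKS, v)


def simulate(
    p: CatchmentParameters,
    grid: TimeGrid,
    interventions: InterventionSet | None = None,
    catalogue: Sequence | None = None,
    state0: ModelState | None = None,
    record: bool = True,
    magnitude_overrides: Mapping | None = None,
    t_offset: float = 0.0,
) -> Trajectory:
    """Run one catchment over ``grid``; the one-stop model runner.

    ``t_offset`` shifts model time (weeks) when continuing from a saved
    state partway through a longer calendar, so intervention start dates
    stay anchored to the calendar of the *original* run start.
    """
    schedule = None
    if interventions is not None and len(interventions) > 0:
        catalogue = default_catalogue() if catalogue is None else list(catalogue)
        by_id = catalogue_by_id(catalogue)
        unknown = [m for m in interventions if m not in by_id]
        if unknown:
            raise ArgumentError(f"unknown intervention ids: {unknown}")
        specs = [by_id[m] for m in interventions]
        schedule = ParamSchedule(
            p,
            specs,
            grid.start_date,
            magnitude_overrides=dict(magnitude_overrides) if magnitude_overrides else None,
        )
    model = CatchmentModel(p, schedule)
    if t_offset:
        model = _ShiftedModel(model, t_offset)
    s0 = state0 if state0 is not None else initial_state(p)
    return integrate(s0, model, grid, record=record)


class _ShiftedModel:
    """Evaluator wrapper offsetting model time (used when resuming runs)."""

    def __init__(self, inner: CatchmentModel, offset: float):
        self._inner = inner
        self._offset = offset
        self.names = inner.names

    def rates_array(self, values, t):
        return self._inner.rates_array(values, t + self._offset)

    def aux_array(self, values, t):
        return self._inner.aux_array(values, t + self._offset)


def yearly_output_metrics(traj: Trajectory) -> dict[str, np.ndarray]:
    """Aggregate a trajectory to per-model-year output metrics.

    Event metrics are differenced from cumulative stocks at 52-week
    boundaries; prevalence and waiting times are step-weighted yearly
    means.  A partial final year is excluded with a warning.
    """
    spw = traj.grid.steps_per_week
    steps_per_year = WEEKS_PER_YEAR * spw
    n_years = traj.grid.horizon_weeks // WEEKS_PER_YEAR
    if n_years < 1:
        raise ArgumentError("trajectory must cover at least one model year")
    if traj.grid.horizon_weeks % WEEKS_PER_YEAR:
        warnings.warn("partial final model year excluded from yearly metrics")

    bounds = np.arange(n_years + 1) * steps_per_year
    metrics: dict[str, np.ndarray] = {}
    event_names = {
        "suicides": "cum_suicides",
        "self_harm_hospitalisations": "cum_selfharm_hospitalisations",
        "ed_presentations": "cum_ed_presentations",
        "gp_consultations": "cum_gp_consultations",
        "specialist_consultations": "cum_specialist_consultations",
        "cmhc_contacts": "cum_cmhc_contacts",
        "inpatient_admissions": "cum_inpatient_admissions",
        "disengagements": "cum_disengagements",
    }
    for metric, stock in event_names.items():
        series = traj.series(stock)
        metrics[metric] = np.diff(series[bounds], axis=0)
    for aux in ("distress_prevalence", "waiting_time_gp", "waiting_time_specialist"):
        if aux in traj.auxiliaries:
            series = traj.aux(aux)
            metrics[aux] = np.array(
                [series[bounds[i]: bounds[i + 1] + 1].mean(axis=0) for i in range(n_years)]
            )
    if "population" in traj.auxiliaries:
        series = traj.aux("population")
        metrics["mean_population"] = np.array(
            [series[bounds[i]: bounds[i + 1] + 1].mean(axis=0) for i in range(n_years)]
        )
    return metrics
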