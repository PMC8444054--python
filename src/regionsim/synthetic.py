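"""Synthetic ten-catchment state and synthetic calibration series.

No machine-readable regional parameter tables or historical series are
available, so the package ships a generator that emulates the *published
heterogeneity* of a ten-catchment state: populations between roughly
243 000 and 1.57 million, mean yearly suicide rates between 7.61 and 12.18
per 100 000, per-capita emergency department presentation rates that are
markedly higher in remote catchments (widening the reach of safety
planning there), and service capacity slack and growth that range from
comfortable (metropolitan) to starved (remote).  The numeric profiles are
generator defaults, not claims about any real region.

Suicide-risk parameters are calibrated per catchment by an inner bisection
so the baseline run hits the catchment's target suicide rate; synthetic
"observed" series are produced by running the model under known true
parameters and applying multiplicative lognormal noise, which keeps the
series positive as the MAPE objective requires.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import ObservedSeries
from .engine import build_time_grid
from .errors import ArgumentError, RegionsimError
from .model import simulate, yearly_output_metrics
from .params import CatchmentParameters

__all__ = [
    "CatchmentProfile",
    "generate_state",
    "generate_observed_series",
    "profile_to_parameters",
    "CALIBRATION_METRICS",
]

#: Metric subset emitted as synthetic observed series (all strictly positive).
CALIBRATION_METRICS = (
    "suicides",
    "self_harm_hospitalisations",
    "ed_presentations",
    "gp_consultations",
    "inpatient_admissions",
    "distress_prevalence",
)

#: Printed ranges the synthetic state must span.
POPULATION_RANGE = (243_000.0, 1_570_000.0)
SUICIDE_RATE_RANGE = (7.61, 12.18)  # per 1e5 per year

_CLASS_CYCLE = (
    "metro", "remote", "regional", "metro", "metro",
    "remote", "regional", "metro", "regional", "metro",
)


@dataclass(frozen=True)
class CatchmentProfile:
    """High-level description from which full parameters are derived."""

    name: str
    population: float
    density_class: str  # metro | regional | remote
    disadvantage_index: float  # standardised score, higher = more disadvantaged
    target_suicide_rate: float  # per 1e5 per year
    ed_presentation_multiplier: float
    capacity_slack: float  # capacity / approximate steady demand

    def __post_init__(self) -> None:
        if not 2e5 <= self.population <= 2e6:
            raise ArgumentError(f"population {self.population} outside [2e5, 2e6]")
        if not 6.0 <= self.target_suicide_rate <= 14.0:
            raise ArgumentError(
                f"target suicide rate {self.target_suicide_rate} outside [6, 14]"
            )
        if self.density_class not in ("metro", "regional", "remote"):
            raise ArgumentError(f"unknown density class {self.density_class!r}")


def _sample_profile(rng: np.random.Generator, i: int, cls: str) -> CatchmentProfile:
    if cls == "metro":
        pop = rng.uniform(8.0e5, POPULATION_RANGE[1])
        rate = rng.uniform(SUICIDE_RATE_RANGE[0], 10.2)
        ed_mult = rng.uniform(0.8, 1.1)
        slack = rng.uniform(1.15, 1.40)
        dis = rng.normal(-0.5, 0.4)
    elif cls == "regional":
        pop = rng.uniform(3.5e5, 9.0e5)
        rate = rng.uniform(9.0, SUICIDE_RATE_RANGE[1])
        ed_mult = rng.uniform(1.0, 1.4)
        slack = rng.uniform(0.95, 1.15)
        dis = rng.normal(0.3, 0.4)
    else:  # remote
        pop = rng.uniform(POPULATION_RANGE[0], 4.5e5)
        rate = rng.uniform(9.5, SUICIDE_RATE_RANGE[1])
        ed_mult = rng.uniform(1.5, 2.0)
        slack = rng.uniform(0.70, 0.88)
        dis = rng.normal(1.0, 0.4)
    return CatchmentProfile(
        name=f"catchment_{i + 1:02d}_{cls}",
        population=float(pop),
        density_class=cls,
        disadvantage_index=float(dis),
        target_suicide_rate=float(rate),
        ed_presentation_multiplier=float(ed_mult),
        capacity_slack=float(slack),
    )


def profile_to_parameters(
    profile: CatchmentProfile, rng: np.random.Generator | None = None
) -> CatchmentParameters:
    """Explicit profile → parameter mapping (before risk calibration).

    Service capacities are set to ``capacity_slack`` times an analytic
    approximation of steady-state demand, so a slack below one produces a
    genuinely congested service network.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    base = CatchmentParameters(name=profile.name)
    pop = profile.population
    prev0 = float(np.clip(0.185 + 0.012 * profile.disadvantage_index, 0.15, 0.24))
    ed_rate = base.ed_presentation_rate * profile.ed_presentation_multiplier

    # approximate steady demand on each service channel
    dnc = 0.80 * prev0 * pop  # distressed residents outside care
    gp_inflow = base.help_seeking_rate * (1.0 - base.direct_online_fraction) * dnc
    rf = base.referral_fractions
    sp_demand = rf["specialist"] * gp_inflow
    cm_demand = rf["cmhc"] * gp_inflow
    attempts = base.attempt_rate_distressed_untreated * prev0 * pop
    inp_demand = rf["inpatient"] * gp_inflow + (
        base.hospitalisation_fraction_of_attempts * attempts
    )

    slack = profile.capacity_slack
    if profile.density_class == "remote":
        growth = {k: float(rng.uniform(0.000, 0.010)) for k in ("gp", "specialist", "cmhc", "inpatient")}
    elif profile.density_class == "regional":
        growth = {k: float(rng.uniform(0.005, 0.018)) for k in ("gp", "specialist", "cmhc", "inpatient")}
    else:
        growth = {k: float(rng.uniform(0.010, 0.028)) for k in ("gp", "specialist", "cmhc", "inpatient")}

    p = base.copy()
    p.name = profile.name
    p.initial_population = pop
    p.initial_distress_prevalence = prev0
    p.ed_presentation_rate = ed_rate
    p.gp_capacity = slack * gp_inflow
    p.specialist_capacity = slack * sp_demand
    p.cmhc_capacity = slack * cm_demand
    p.inpatient_capacity = slack * inp_demand * base.inpatient_los
    p.capacity_growth = growth
    p.validate()
    return p


def baseline_suicide_rate(
    p: CatchmentParameters, horizon_years: int = 10, steps_per_week: int = 8
) -> float:
    """Mean yearly suicides per 1e5 residents over a baseline run."""
    grid = build_time_grid(dt.date(2011, 1, 1), horizon_years, steps_per_week)
    traj = simulate(p, grid)
    metrics = yearly_output_metrics(traj)
    yearly = metrics["suicides"]
    mean_pop = metrics["mean_population"].mean()
    return float(yearly.mean() / mean_pop * 1e5)


_RISK_PATHS = (
    "attempt_rate_distressed_untreated",
    "attempt_rate_in_care",
    "attempt_rate_postdischarge",
)


def _scale_risk(p: CatchmentParameters, m: float) -> CatchmentParameters:
    q = p.copy()
    for path in _RISK_PATHS:
        setattr(q, path, m * getattr(p, path))
    q.validate()
    return q


def calibrate_risk_to_target(
    p: CatchmentParameters,
    target_rate: float,
    rel_tol: float = 0.02,
    max_iter: int = 40,
) -> CatchmentParameters:
    """Bisection on a joint attempt-rate multiplier until the baseline mean
    yearly suicide rate matches the target (relative tolerance)."""
    lo, hi = 0.1, 8.0
    rate_lo = baseline_suicide_rate(_scale_risk(p, lo))
    rate_hi = baseline_suicide_rate(_scale_risk(p, hi))
    if not rate_lo <= target_rate <= rate_hi:
        raise RegionsimError(
            f"risk calibration bracket failed for {p.name!r}: "
            f"[{rate_lo:.2f}, {rate_hi:.2f}] does not cover {target_rate:.2f}"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        rate = baseline_suicide_rate(_scale_risk(p, mid))
        if abs(rate - target_rate) / target_rate < rel_tol:
            return _scale_risk(p, mid)
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    raise RegionsimError(f"risk calibration did not converge for {p.name!r}")


def generate_state(seed: int, n_catchments: int = 10) -> list[CatchmentParameters]:
    """Generate the synthetic state: heterogeneous catchment parameter sets.

    Deterministic given the seed.  The class pattern guarantees, for
    ``n_catchments >= 2``, at least one remote catchment (high ED
    presentation rates, starved capacity) and at least one metropolitan
    catchment with comfortable capacity slack.
    """
    if n_catchments < 1:
        raise ArgumentError("n_catchments must be >= 1")
    rng = np.random.default_rng(seed)
    classes = [
        _CLASS_CYCLE[i % len(_CLASS_CYCLE)] for i in range(n_catchments)
    ]
    if n_catchments >= 2 and "remote" not in classes:
        classes[1] = "remote"
    out = []
    for i, cls in enumerate(classes):
        profile = _sample_profile(rng, i, cls)
        p = profile_to_parameters(profile, rng)
        p = calibrate_risk_to_target(p, profile.target_suicide_rate)
        out.append(p)
    return out


def generate_observed_series(
    p: CatchmentParameters,
    years: Sequence[int] = tuple(range(2011, 2021)),
    noise_cv: float = 0.0,
    seed: int = 0,
    steps_per_week: int = 8,
) -> list[ObservedSeries]:
    """Synthetic yearly "observed" series from a model run under ``p``.

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean-one) is applied independently per point; ``cv = 0``
    returns the model outputs exactly.
    """
    if noise_cv < 0:
        raise ArgumentError("noise_cv must be >= 0")
    years = tuple(int(y) for y in years)
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ArgumentError("years must be strictly increasing")
    start_year = years[0]
    n_years = years[-1] - start_year + 1
    grid = build_time_grid(dt.date(start_year, 1, 1), n_years, steps_per_week)
    metrics = yearly_output_metrics(simulate(p, grid))

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    out = []
    for metric in CALIBRATION_METRICS:
        series = np.asarray(metrics[metric], dtype=float)
        values = []
        for y in years:
            v = series[y - start_year]
            if noise_cv > 0:
                v *= float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))
            values.append(float(v))
        out.append(ObservedSeries(metric, years, tuple(values)))
    return out
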