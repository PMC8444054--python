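"""Catchment parameterisation: container, validation, config file IO.

A :class:`CatchmentParameters` instance holds the full numeric description
of one regional catchment: demography, psychological distress dynamics,
the mental health service network (capacities, referral pathways, queue
behaviour) and suicidal-behaviour risk.  All rates are per week unless a
field name says otherwise; fractions are dimensionless in [0, 1].

Parameters are addressed by dotted *paths* (``"help_seeking_rate"``,
``"capacity_growth.specialist"``) by the intervention and calibration
machinery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["CatchmentParameters", "SERVICES", "load_catchment", "save_catchment"]

#: Capacity-constrained service channels (online care is unconstrained).
SERVICES = ("gp", "specialist", "cmhc", "inpatient")

SCHEMA_VERSION = 1


def _default_capacity_growth() -> dict[str, float]:
    # Baseline "business as usual" yearly fractional capacity growth.
    return {"gp": 0.015, "specialist": 0.015, "cmhc": 0.015, "inpatient": 0.01}


def _default_referral_fractions() -> dict[str, float]:
    # Split of GP care completions across onward pathways.
    return {
        "specialist": 0.25,
        "cmhc": 0.10,
        "inpatient": 0.02,
        "online": 0.13,
        "discharge": 0.50,
    }


@dataclass
class CatchmentParameters:
    """Full parameter set for one catchment.

    The defaults describe a nominal metropolitan catchment of one million
    residents with modest slack in service capacity; the synthetic-state
    generator rescales them per catchment profile.
    """

    name: str = "nominal"

    # --- demography ------------------------------------------------------
    initial_population: float = 1_000_000.0
    birth_rate: float = 0.00024  # births /week per capita (~1.25 %/yr)
    migration_rate: float = 0.0001  # net inward /week per capita
    background_mortality: float = 0.00013  # non-suicide deaths /week per capita

    # --- psychological distress -----------------------------------------
    initial_distress_prevalence: float = 0.185  # K10 >= 16 fraction
    distress_onset_rate: float = 0.0025  # low -> distressed, /week
    distress_recovery_untreated: float = 0.011  # distressed -> low, /week
    distress_recovery_in_care: float = 0.040  # in-care -> low, /week
    waiting_recovery_factor: float = 0.2  # recovery multiplier while queued
    disengaged_recovery_factor: float = 0.5  # recovery multiplier once disengaged

    # --- help seeking and service pathways ------------------------------
    help_seeking_rate: float = 0.015  # distressed-not-in-care -> queue, /week
    reengagement_factor: float = 0.25  # disengaged re-seek multiplier
    direct_online_fraction: float = 0.10  # help seekers going straight online
    ed_presentation_rate: float = 0.002  # MH-related ED, /week per distressed

    gp_capacity: float = 2000.0  # new GP intakes /week
    specialist_capacity: float = 520.0  # psychiatrist + allied intakes /week
    cmhc_capacity: float = 210.0  # community MH places /week
    inpatient_capacity: float = 110.0  # psychiatric beds
    capacity_growth: dict[str, float] = field(default_factory=_default_capacity_growth)
    referral_fractions: dict[str, float] = field(
        default_factory=_default_referral_fractions
    )

    gp_care_duration: float = 8.0  # weeks in GP-led care
    specialist_care_duration: float = 26.0
    cmhc_care_duration: float = 26.0
    online_care_duration: float = 12.0
    inpatient_los: float = 2.0  # weeks, mean length of stay
    min_intake_wait: float = 1.0  # weeks; queue clearance floor

    # --- disengagement ---------------------------------------------------
    waiting_tolerance: float = 4.0  # weeks; scale of wait-driven disengagement
    disengagement_max_rate: float = 0.25  # /week, saturating maximum
    dissatisfaction_rate: float = 0.012  # in-care -> disengaged, /week
    max_waiting_time: float = 52.0  # weeks; cap on the reported wait

    # --- suicidal behaviour ----------------------------------------------
    attempt_rate_distressed_untreated: float = 3.0e-4  # /week
    attempt_rate_in_care: float = 1.0e-4  # /week
    attempt_rate_postdischarge: float = 6.0e-3  # /week
    hospitalisation_fraction_of_attempts: float = 0.33
    case_fatality: float = 0.05  # fraction of attempts that are fatal
    postdischarge_window: float = 26.0  # weeks of elevated post-discharge risk
    postdischarge_recovery_fraction: float = 0.4  # exit share going to low distress

    # --- safety planning reach ------------------------------------------
    safety_planning_strength: float = 0.0  # active only under intervention
    safety_planning_reach_scale: float = 250.0  # reach = min(1, scale * ed rate)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming every invalid field."""
        problems: list[str] = []
        fractions = (
            "initial_distress_prevalence",
            "waiting_recovery_factor",
            "disengaged_recovery_factor",
            "reengagement_factor",
            "direct_online_fraction",
            "hospitalisation_fraction_of_attempts",
            "case_fatality",
            "postdischarge_recovery_fraction",
            "safety_planning_strength",
        )
        for f in dataclasses.fields(self):
            if f.name == "name" or not isinstance(getattr(self, f.name), (int, float)):
                continue
            v = getattr(self, f.name)
            if not v >= 0:
                problems.append(f"{f.name} must be >= 0, got {v}")
        for f in fractions:
            v = getattr(self, f)
            if not 0 <= v <= 1:
                problems.append(f"{f} must be in [0, 1], got {v}")
        rf = self.referral_fractions
        missing = set(_default_referral_fractions()) - set(rf)
        if missing:
            problems.append(f"referral_fractions missing keys {sorted(missing)}")
        elif abs(sum(rf.values()) - 1.0) > 1e-9:
            problems.append(f"referral_fractions must sum to 1, got {sum(rf.values())}")
        if set(self.capacity_growth) != set(SERVICES):
            problems.append(
                f"capacity_growth must have keys {SERVICES}, got {sorted(self.capacity_growth)}"
            )
        if self.attempt_rate_in_care > self.attempt_rate_distressed_untreated:
            problems.append(
                "attempt_rate_in_care must not exceed attempt_rate_distressed_untreated"
            )
        if problems:
            raise ConfigurationError(
                "invalid catchment parameters: " + "; ".join(problems)
            )

    # -- dotted-path access ----------------------------------------------
    def get_path(self, path: str) -> float:
        head, _, rest = path.partition(".")
        try:
            v = getattr(self, head)
        except AttributeError:
            raise ConfigurationError(f"unknown parameter path {path!r}") from None
        if rest:
            try:
                return v[rest]
            except (TypeError, KeyError):
                raise ConfigurationError(f"unknown parameter path {path!r}") from None
        if not isinstance(v, (int, float)):
            raise ConfigurationError(f"parameter path {path!r} is not numeric")
        return float(v)

    def with_path(self, path: str, value: float) -> "CatchmentParameters":
        """Return a copy with one dotted path replaced (validated)."""
        self.get_path(path)  # existence check
        new = self.copy()
        head, _, rest = path.partition(".")
        if rest:
            getattr(new, head)[rest] = float(value)
        else:
            setattr(new, head, float(value))
        new.validate()
        return new

    def copy(self) -> "CatchmentParameters":
        return dataclasses.replace(
            self,
            capacity_growth=dict(self.capacity_growth),
            referral_fractions=dict(self.referral_fractions),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, dict):
                d[k] = {kk: float(vv) for kk, vv in v.items()}
            elif isinstance(v, (int, float)):
                d[k] = float(v)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CatchmentParameters":
        d = dict(d)
        d.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown catchment parameter fields: {sorted(unknown)}"
            )
        return cls(**d)


def load_catchment(path: str | Path) -> CatchmentParameters:
    """Read one catchment parameter file (YAML mapping)."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"catchment parameter file not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"catchment file {p} is not a mapping")
    return CatchmentParameters.from_dict(data)


def save_catchment(params: CatchmentParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
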