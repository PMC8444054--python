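"""Intervention catalogue and application of direct effects to parameters.

Only the *direct* effects of an intervention are specified here — a small
set of (parameter path, mode, magnitude) modifications switched on from the
intervention's start date with a linear ramp-in.  All indirect consequences
(queue relief or congestion, changed case-mix, altered recovery) emerge
from the model structure, which is why combined interventions need not act
additively.

Three of the thirteen catalogue entries (``gp_capacity``,
``online_services``, ``ed_aftercare_outreach``) are reconstructions: the
published analyses name only ten interventions, and these placeholders
complete the catalogue with plausible service-side measures.  They are
flagged via ``InterventionSpec.reconstructed``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .engine import WEEKS_PER_YEAR
from .errors import ArgumentError, ConfigurationError
from .params import CatchmentParameters

__all__ = [
    "Effect",
    "InterventionSpec",
    "InterventionSet",
    "default_catalogue",
    "apply_interventions",
    "ParamSchedule",
    "date_to_model_weeks",
    "load_catalogue",
    "save_catalogue",
]

DEFAULT_START = dt.date(2021, 1, 1)
DEFAULT_RAMP_WEEKS = 13.0  # one quarter to full effect

MODES = ("multiply", "add", "replace")


def date_to_model_weeks(start_date: dt.date, date: dt.date) -> float:
    """Convert a calendar date to model weeks (52-week model years)."""
    day_frac = (date.timetuple().tm_yday - start_date.timetuple().tm_yday) / 365.25
    return WEEKS_PER_YEAR * ((date.year - start_date.year) + day_frac)


@dataclass(frozen=True)
class Effect:
    """One direct parameter modification."""

    path: str
    mode: str  # multiply | add | replace
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown effect mode {self.mode!r}")
        if self.mode == "multiply" and not self.magnitude > 0:
            raise ConfigurationError(
                f"multiply magnitude must be > 0, got {self.magnitude}"
            )


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention: id, display name and its direct effects."""

    id: str
    name: str
    effects: tuple[Effect, ...]
    start_time: dt.date = DEFAULT_START
    ramp_weeks: float = DEFAULT_RAMP_WEEKS
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if not self.effects:
            raise ConfigurationError(f"intervention {self.id!r} has no effects")
        if self.ramp_weeks < 0:
            raise ConfigurationError("ramp_weeks must be >= 0")

    def validate_paths(self, params: CatchmentParameters) -> None:
        for e in self.effects:
            params.get_path(e.path)  # raises ConfigurationError if unknown


class InterventionSet:
    """Unordered subset of catalogue ids (hashable, duplicate-free)."""

    def __init__(self, members: Iterable[str] = ()):
        members = tuple(members)
        if len(set(members)) != len(members):
            raise ArgumentError(f"duplicate intervention ids in {members}")
        self.members: tuple[str, ...] = tuple(sorted(members))

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    def __eq__(self, other):
        return isinstance(other, InterventionSet) and self.members == other.members

    def __hash__(self):
        return hash(self.members)

    def __repr__(self):
        return f"InterventionSet({list(self.members)})"

    def label(self) -> str:
        return "+".join(self.members) if self.members else "(baseline)"


def default_catalogue() -> list[InterventionSpec]:
    """The thirteen-intervention catalogue with default direct-effect sizes.

    Magnitudes are generator defaults chosen so that single-intervention
    effects on the synthetic state fall in plausible published ranges; they
    are overridable via catalogue files and are sampled (±20 %) by the
    sensitivity analysis.
    """
    E = Effect
    specs = [
        InterventionSpec(
            "post_attempt_care",
            "Post-suicide attempt care",
            (E("attempt_rate_postdischarge", "multiply", 0.40),),
        ),
        InterventionSpec(
            "safety_planning",
            "Safety planning in emergency departments",
            (E("safety_planning_strength", "add", 0.10),),
        ),
        InterventionSpec(
            "care_coordination",
            "Technology-enabled care coordination",
            (
                E("dissatisfaction_rate", "multiply", 0.40),
                E("disengagement_max_rate", "multiply", 0.40),
                E("reengagement_factor", "multiply", 3.0),
            ),
        ),
        InterventionSpec(
            "family_psychoeducation",
            "Family psychoeducation and support programmes",
            (
                E("distress_onset_rate", "multiply", 0.975),
                E("help_seeking_rate", "multiply", 1.15),
            ),
        ),
        InterventionSpec(
            "social_connectedness",
            "Social-connectedness programmes",
            (E("distress_onset_rate", "multiply", 0.94),),
        ),
        InterventionSpec(
            "awareness_campaign",
            "Community awareness campaigns",
            (E("help_seeking_rate", "multiply", 1.30),),
        ),
        InterventionSpec(
            "psychiatrist_capacity",
            "Psychiatrist capacity growth increase",
            (E("capacity_growth.specialist", "add", 0.020),),
        ),
        InterventionSpec(
            "allied_health_capacity",
            "Allied mental health capacity growth increase",
            (E("capacity_growth.specialist", "add", 0.010),),
        ),
        InterventionSpec(
            "community_acute_care",
            "Community-based acute care services",
            (
                E("capacity_growth.inpatient", "add", 0.030),
                E("attempt_rate_postdischarge", "multiply", 0.92),
            ),
        ),
        InterventionSpec(
            "cmhc_capacity",
            "Community mental healthcare capacity growth increase",
            (E("capacity_growth.cmhc", "add", 0.030),),
        ),
        InterventionSpec(
            "gp_capacity",
            "General practice capacity growth increase",
            (E("capacity_growth.gp", "add", 0.020),),
            reconstructed=True,
        ),
        InterventionSpec(
            "online_services",
            "Expanded online mental health services",
            (E("direct_online_fraction", "add", 0.05),),
            reconstructed=True,
        ),
        InterventionSpec(
            "ed_aftercare_outreach",
            "Assertive aftercare outreach following ED presentation",
            (E("attempt_rate_postdischarge", "multiply", 0.85),),
            reconstructed=True,
        ),
    ]
    return specs


def catalogue_by_id(catalogue: Sequence[InterventionSpec]) -> dict[str, InterventionSpec]:
    by_id = {s.id: s for s in catalogue}
    if len(by_id) != len(catalogue):
        raise ConfigurationError("duplicate intervention ids in catalogue")
    return by_id


class ParamSchedule:
    """Time-dependent effective parameter values for an intervention set.

    Compiles the member interventions' effects against a base parameter set
    and serves, for any model time ``t`` (weeks), the dict of overridden
    parameter paths.  Magnitudes may be scalars or 1-d arrays of equal
    length (a *batch*): one column per scenario or per sensitivity draw.

    Each effect ramps linearly from its start to start+ramp; a multiply
    magnitude ``m`` acts as ``1 + (m − 1)·r(t)``, an add magnitude ``a`` as
    ``a·r(t)``.  Multiplies compose commutatively; adds are applied after
    multiplies; two ``replace`` effects on one path are a configuration
    error.
    """

    def __init__(
        self,
        base: CatchmentParameters,
        specs: Sequence[InterventionSpec],
        grid_start: dt.date,
        magnitude_overrides: dict[tuple[str, str], np.ndarray | float] | None = None,
    ):
        self.base = base
        self._by_path: dict[str, list[tuple[str, object, float, float]]] = {}
        self.batch_size: int | None = None
        ends = [0.0]
        starts = []
        for spec in specs:
            spec.validate_paths(base)
            s = date_to_model_weeks(grid_start, spec.start_time)
            e = s + spec.ramp_weeks
            starts.append(s)
            ends.append(e)
            for eff in spec.effects:
                mag = eff.magnitude
                if magnitude_overrides is not None:
                    mag = magnitude_overrides.get((spec.id, eff.path), mag)
                mag = np.asarray(mag, dtype=float) if np.ndim(mag) else float(mag)
                if np.ndim(mag):
                    if self.batch_size not in (None, mag.shape[0]):
                        raise ArgumentError("inconsistent batch sizes in magnitudes")
                    self.batch_size = mag.shape[0]
                self._by_path.setdefault(eff.path, []).append(
                    (eff.mode, mag, s, spec.ramp_weeks)
                )
        for path, effs in self._by_path.items():
            if sum(1 for m, *_ in effs if m == "replace") > 1:
                raise ConfigurationError(
                    f"conflicting replace effects on parameter {path!r}"
                )
        self._t_on = min(starts) if starts else np.inf
        self._t_full = max(ends)
        self._full_cache: dict[str, object] | None = None

    @property
    def paths(self) -> tuple[str, ...]:
        return tuple(self._by_path)

    def overrides(self, t_weeks: float) -> dict[str, object]:
        """Effective values for every modified path at model time ``t``."""
        if t_weeks < self._t_on:
            return {}
        if t_weeks >= self._t_full:
            if self._full_cache is None:
                self._full_cache = self._compute(self._t_full)
            return self._full_cache
        return self._compute(t_weeks)

    def _compute(self, t: float) -> dict[str, object]:
        out: dict[str, object] = {}
        for path, effs in self._by_path.items():
            base = self.base.get_path(path)
            mult: object = 1.0
            add: object = 0.0
            value = base
            for mode, mag, start, ramp in effs:
                if ramp > 0:
                    r = min(max((t - start) / ramp, 0.0), 1.0)
                else:
                    r = 1.0 if t >= start else 0.0
                if mode == "multiply":
                    mult = mult * (1.0 + (mag - 1.0) * r)
                elif mode == "add":
                    add = add + mag * r
                else:  # replace
                    value = base + (mag - base) * r
            out[path] = value * mult + add
        return out


def apply_interventions(
    p: CatchmentParameters,
    interventions: InterventionSet,
    t_weeks: float,
    catalogue: Sequence[InterventionSpec] | None = None,
    grid_start: dt.date = dt.date(2011, 1, 1),
) -> CatchmentParameters:
    """Effective parameters at model time ``t`` under an intervention set.

    Before every member's start date the input is returned unchanged; after
    start+ramp all effects are fully composed; in between, linearly ramped.
    """
    catalogue = default_catalogue() if catalogue is None else list(catalogue)
    by_id = catalogue_by_id(catalogue)
    unknown = [m for m in interventions if m not in by_id]
    if unknown:
        raise ConfigurationError(f"unknown intervention ids: {unknown}")
    specs = [by_id[m] for m in interventions]
    schedule = ParamSchedule(p, specs, grid_start)
    out = p
    for path, value in schedule.overrides(t_weeks).items():
        out = out.with_path(path, float(value))
    return out


# ---------------------------------------------------------------------------
# catalogue serialisation


def save_catalogue(catalogue: Sequence[InterventionSpec], path: str | Path) -> None:
    items = []
    for s in catalogue:
        items.append(
            {
                "id": s.id,
                "name": s.name,
                "start_time": s.start_time.isoformat(),
                "ramp_weeks": s.ramp_weeks,
                "reconstructed": s.reconstructed,
                "effects": [
                    {"path": e.path, "mode": e.mode, "magnitude": e.magnitude}
                    for e in s.effects
                ],
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump({"schema_version": 1, "interventions": items}, fh, sort_keys=False)


def load_catalogue(path: str | Path) -> list[InterventionSpec]:
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"catalogue file not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh)
    try:
        items = data["interventions"]
    except (TypeError, KeyError):
        raise ConfigurationError(f"catalogue file {p} has no 'interventions' key")
    specs = []
    for item in items:
        specs.append(
            InterventionSpec(
                id=item["id"],
                name=item.get("name", item["id"]),
                effects=tuple(
                    Effect(e["path"], e["mode"], float(e["magnitude"]))
                    for e in item["effects"]
                ),
                start_time=dt.date.fromisoformat(str(item.get("start_time", DEFAULT_START))),
                ramp_weeks=float(item.get("ramp_weeks", DEFAULT_RAMP_WEEKS)),
                reconstructed=bool(item.get("reconstructed", False)),
            )
        )
    return specs
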