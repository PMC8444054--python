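"""Fixed-step stock-and-flow integration on a weekly simulation calendar.

The engine is deliberately generic: it knows about stocks (named
accumulations), net flow rates (per week) and a :class:`TimeGrid`, and
nothing about mental health services.  The default integration scheme is
explicit Euler with a step of one-eighth of a week (0.875 days), the
standard fixed-step choice in system dynamics practice.

Two evaluator interfaces are accepted by :func:`integrate`:

* a *mapping evaluator* ``f(state: ModelState, t_weeks) -> {stock: rate}``,
  convenient for small models and tests; and
* a *vector evaluator* object exposing ``rates_array(values, t_weeks)``
  (and optionally ``aux_array``) operating directly on the state vector.
  This is the fast path used by the core model and by batched scenario
  sweeps, where ``values`` has shape ``(n_stocks, batch)``.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ArgumentError, ModelDefinitionError, NumericalError

__all__ = [
    "WEEKS_PER_YEAR",
    "TimeGrid",
    "ModelState",
    "Trajectory",
    "build_time_grid",
    "euler_step",
    "integrate",
]

#: Model-year convention: one model year is exactly 52 weeks.  Calendar
#: drift of ~1.25 days per year against the Gregorian calendar is accepted.
WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class TimeGrid:
    """Uniform weekly simulation grid.

    Attributes
    ----------
    start_date:
        Calendar date of step 0.
    horizon_weeks:
        Total span of the grid in weeks.
    steps_per_week:
        Number of Euler steps per week; ``dt_weeks = 1/steps_per_week``.
    """

    start_date: dt.date
    horizon_weeks: int
    steps_per_week: int

    def __post_init__(self) -> None:
        if self.horizon_weeks < 1 or self.steps_per_week < 1:
            raise ArgumentError(
                "horizon_weeks and steps_per_week must be positive integers"
            )

    @property
    def dt_weeks(self) -> float:
        return 1.0 / self.steps_per_week

    @property
    def dt_days(self) -> float:
        return 7.0 / self.steps_per_week

    @property
    def n_steps(self) -> int:
        return self.horizon_weeks * self.steps_per_week

    def time_weeks(self, step: int) -> float:
        """Time of step ``step`` in weeks since ``start_date``."""
        return step / self.steps_per_week

    def times_weeks(self) -> np.ndarray:
        """All step-boundary times in weeks (length ``n_steps + 1``)."""
        return np.arange(self.n_steps + 1) / self.steps_per_week

    def date_of(self, step: int) -> dt.date:
        """Calendar date of a step boundary (floor to whole days)."""
        return self.start_date + dt.timedelta(days=int(step * self.dt_days))

    def step_of_week(self, t_weeks: float) -> int:
        """Grid step index closest to a time in weeks."""
        return int(round(t_weeks * self.steps_per_week))


def build_time_grid(
    start_date: dt.date, horizon_years: int, steps_per_week: int = 8
) -> TimeGrid:
    """Build the simulation grid; one model year is 52 weeks.

    The default ``steps_per_week=8`` gives dt = 0.875 days.
    """
    if horizon_years < 1 or steps_per_week < 1:
        raise ArgumentError("horizon_years and steps_per_week must be >= 1")
    return TimeGrid(start_date, WEEKS_PER_YEAR * horizon_years, steps_per_week)


@dataclass
class ModelState:
    """Stock values at one time point.

    Stocks are kept in a fixed declaration order so that state vectors are
    reproducible; values may be scalars or 1-d arrays (batched states).
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.names):
            raise ArgumentError(
                f"state has {self.values.shape[0]} values for {len(self.names)} stocks"
            )

    @classmethod
    def from_mapping(cls, stocks: Mapping[str, float]) -> "ModelState":
        names = tuple(stocks)
        return cls(names, np.array([stocks[n] for n in names], dtype=float))

    def __getitem__(self, name: str):
        return self.values[self.names.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def copy(self) -> "ModelState":
        return ModelState(self.names, self.values.copy())


@dataclass
class Trajectory:
    """Stock and auxiliary time series over a :class:`TimeGrid`.

    ``states`` has shape ``(n_steps + 1, n_stocks)`` (an extra trailing
    batch axis when integrating batched states); each auxiliary series has
    length ``n_steps + 1``.
    """

    grid: TimeGrid
    stock_names: tuple[str, ...]
    states: np.ndarray
    auxiliaries: dict[str, np.ndarray] = field(default_factory=dict)

    def series(self, stock: str) -> np.ndarray:
        return self.states[:, self.stock_names.index(stock)]

    def aux(self, name: str) -> np.ndarray:
        return self.auxiliaries[name]

    def final_state(self) -> ModelState:
        return ModelState(self.stock_names, self.states[-1].copy())

    def state_at_week(self, t_weeks: float) -> ModelState:
        k = self.grid.step_of_week(t_weeks)
        return ModelState(self.stock_names, self.states[k].copy())

    def to_frame(self):
        """Tidy long-format DataFrame: time_weeks, date, variable, value."""
        import pandas as pd

        t = self.grid.times_weeks()
        dates = [self.grid.date_of(k) for k in range(self.grid.n_steps + 1)]
        frames = []
        for j, name in enumerate(self.stock_names):
            frames.append(
                pd.DataFrame(
                    {
                        "time_weeks": t,
                        "date": dates,
                        "variable": name,
                        "value": self.states[:, j],
                    }
                )
            )
        for name, series in self.auxiliaries.items():
            frames.append(
                pd.DataFrame(
                    {"time_weeks": t, "date": dates, "variable": name, "value": series}
                )
            )
        return pd.concat(frames, ignore_index=True)


FlowEvaluator = Callable[[ModelState, float], Mapping[str, float]]


def _rates_to_array(
    state: ModelState, rates: Mapping[str, float], t_weeks: float
) -> np.ndarray:
    unknown = set(rates) - set(state.names)
    if unknown:
        raise ModelDefinitionError(
            f"flow evaluator returned rates for unknown stocks: {sorted(unknown)}"
        )
    out = np.zeros_like(state.values)
    for name, rate in rates.items():
        if not np.all(np.isfinite(rate)):
            raise NumericalError(
                f"non-finite flow rate for stock {name!r} at t={t_weeks} weeks"
            )
        out[state.names.index(name)] = rate
    return out


def euler_step(
    state: ModelState,
    flow_evaluator: FlowEvaluator,
    t_weeks: float,
    dt_weeks: float,
) -> ModelState:
    """One explicit Euler step: ``stock' = stock + dt * net_rate``.

    Stocks are clamped at zero with a warning if a flow overdraws one; the
    default model parameterisation never triggers the clamp.
    """
    rates = _rates_to_array(state, flow_evaluator(state, t_weeks), t_weeks)
    new = state.values + dt_weeks * rates
    if np.any(new < 0):
        warnings.warn(
            f"negative stock clamped to zero at t={t_weeks} weeks", stacklevel=2
        )
        new = np.maximum(new, 0.0)
    return ModelState(state.names, new)


class _MappingAdapter:
    """Wraps a mapping-style evaluator as a vector evaluator."""

    def __init__(self, names: tuple[str, ...], flows: FlowEvaluator, aux=None):
        self.names = names
        self._flows = flows
        self._aux = aux

    def rates_array(self, values: np.ndarray, t_weeks: float) -> np.ndarray:
        state = ModelState(self.names, values)
        return _rates_to_array(state, self._flows(state, t_weeks), t_weeks)

    def aux_array(self, values: np.ndarray, t_weeks: float) -> dict:
        if self._aux is None:
            return {}
        return dict(self._aux(ModelState(self.names, values), t_weeks))


def integrate(
    initial_state: ModelState,
    flow_evaluator,
    grid: TimeGrid,
    auxiliary_evaluator=None,
    record: bool = True,
    check_every: int = 64,
) -> Trajectory:
    """Integrate a model over ``grid`` with repeated Euler steps.

    ``flow_evaluator`` is either a mapping evaluator or an object with a
    ``rates_array(values, t_weeks) -> ndarray`` method (fast path; may also
    provide ``aux_array``).  Deterministic: identical inputs give
    bit-identical trajectories.

    With ``record=False`` only the final state is stored (plus the initial
    one), which the batched scenario sweeps rely on to bound memory.
    Finiteness is verified every ``check_every`` steps and at the end;
    failures name the offending step.
    """
    if hasattr(flow_evaluator, "rates_array"):
        evaluator = flow_evaluator
    else:
        evaluator = _MappingAdapter(
            initial_state.names, flow_evaluator, auxiliary_evaluator
        )
        auxiliary_evaluator = None  # handled through the adapter

    values = np.array(initial_state.values, dtype=float, copy=True)
    n = grid.n_steps
    dt_w = grid.dt_weeks

    aux_fn = getattr(evaluator, "aux_array", None)
    if auxiliary_evaluator is not None:
        aux_fn = lambda v, t: dict(  # noqa: E731
            auxiliary_evaluator(ModelState(initial_state.names, v), t)
        )

    if record:
        states = np.empty((n + 1,) + values.shape)
    else:
        states = np.empty((2,) + values.shape)
    states[0] = values

    aux_records: dict[str, list] = {}

    def _record_aux(k: int, v: np.ndarray, t: float) -> None:
        if aux_fn is None:
            return
        for name, val in aux_fn(v, t).items():
            aux_records.setdefault(name, []).append(val)

    if record:
        _record_aux(0, values, 0.0)
    clamped = 0
    for k in range(n):
        t = k * dt_w
        try:
            rates = evaluator.rates_array(values, t)
        except Exception as exc:  # re-raise with the step attached
            raise type(exc)(f"step {k} (t={t:.4f} weeks): {exc}") from exc
        values = values + dt_w * rates
        if np.any(values < 0):
            clamped += 1
            values = np.maximum(values, 0.0)
        if (k % check_every == 0 or k == n - 1) and not np.all(np.isfinite(values)):
            raise NumericalError(f"non-finite stock value at or before step {k + 1}")
        if record:
            states[k + 1] = values
            _record_aux(k + 1, values, (k + 1) * dt_w)
    if not record:
        states[1] = values
    if clamped:
        warnings.warn(
            f"negative stocks clamped to zero on {clamped} step(s)", stacklevel=2
        )

    auxiliaries = {k: np.asarray(v) for k, v in aux_records.items()}
    return Trajectory(grid, initial_state.names, states, auxiliaries)
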