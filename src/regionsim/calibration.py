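"""Calibration of free parameters to yearly historical series.

The objective is the mean absolute per cent error (MAPE) across all
observed (metric, year) points, minimised with Powell's derivative-free
direction-set method.  Powell's method is unconstrained, so box bounds are
enforced through a smooth sinusoidal reparameterisation
``x = lo + (hi - lo) * (sin(z) + 1) / 2``: every unconstrained iterate maps
to an in-bounds parameter vector, and the optimum is returned on the
original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import TimeGrid
from .errors import AlignmentError, ArgumentError, ConfigurationError
from .model import simulate, yearly_output_metrics
from .params import CatchmentParameters

__all__ = [
    "ObservedSeries",
    "CalibrationProblem",
    "CalibrationResult",
    "mape",
    "calibrate",
    "load_observed_series",
    "save_observed_series",
]


@dataclass(frozen=True)
class ObservedSeries:
    """Yearly historical values for one output metric."""

    metric: str
    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ArgumentError("years and values differ in length")
        if not self.years:
            raise ArgumentError("empty observed series")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ArgumentError("years must be strictly increasing")
        if any(not v > 0 for v in self.values):
            raise ArgumentError(
                f"observed values for {self.metric!r} must be > 0 (MAPE requires it)"
            )


@dataclass
class CalibrationProblem:
    """Free parameters (with bounds), targets and the fixed base parameters."""

    free_parameters: list[tuple[str, float, float, float]]  # path, lo, hi, x0
    targets: list[ObservedSeries]
    fixed: CatchmentParameters

    def __post_init__(self) -> None:
        for path, lo, hi, x0 in self.free_parameters:
            self.fixed.get_path(path)  # existence check
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"invalid bounds for {path!r}: [{lo}, {hi}]")
            if not lo <= x0 <= hi:
                raise ConfigurationError(
                    f"initial value {x0} for {path!r} outside [{lo}, {hi}]"
                )


@dataclass
class CalibrationResult:
    parameters: CatchmentParameters
    values: dict[str, float]
    mape: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    message: str = ""
    trace: list[tuple[float, ...]] = field(default_factory=list)


def mape(
    observed: Sequence[ObservedSeries],
    simulated: Mapping[str, np.ndarray],
    start_year: int,
) -> float:
    """Mean over all observation points of ``100 * |obs - sim| / obs``.

    ``simulated`` maps metric names to per-model-year series whose first
    entry corresponds to ``start_year``.
    """
    errors: list[float] = []
    for series in observed:
        if series.metric not in simulated:
            raise AlignmentError(f"no simulated series for metric {series.metric!r}")
        sim = np.asarray(simulated[series.metric])
        for year, obs in zip(series.years, series.values):
            idx = year - start_year
            if not 0 <= idx < len(sim):
                raise AlignmentError(
                    f"simulated output does not cover {series.metric!r} in {year}"
                )
            errors.append(100.0 * abs(obs - sim[idx]) / obs)
    if not errors:
        raise ArgumentError("no observation points")
    return float(np.mean(errors))


def _to_bounded(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * (np.sin(z) + 1.0) / 2.0


def _from_bounded(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return np.arcsin(frac)


def calibrate(
    problem: CalibrationProblem,
    grid: TimeGrid,
    xtol: float = 1e-4,
    ftol: float = 1e-4,
    max_iterations: int = 200,
) -> CalibrationResult:
    """Fit the free parameters by Powell/MAPE minimisation.

    Deterministic given the initial values.  Non-convergence within
    ``max_iterations`` returns the best-so-far parameters with
    ``converged=False`` rather than raising.
    """
    paths = [fp[0] for fp in problem.free_parameters]
    lo = np.array([fp[1] for fp in problem.free_parameters])
    hi = np.array([fp[2] for fp in problem.free_parameters])
    x0 = np.array([fp[3] for fp in problem.free_parameters])
    start_year = grid.start_date.year
    trace: list[tuple[float, ...]] = []

    def objective_x(x: np.ndarray) -> float:
        p = problem.fixed
        for path, v in zip(paths, x):
            p = p.with_path(path, float(v))
        traj = simulate(p, grid)
        sim = yearly_output_metrics(traj)
        val = mape(problem.targets, sim, start_year)
        trace.append(tuple(x) + (val,))
        return val

    if not paths:
        value = objective_x(x0)
        return CalibrationResult(
            problem.fixed.copy(), {}, value, 0, 1, True, "no free parameters", trace
        )

    z0 = _from_bounded(x0, lo, hi)
    res = minimize(
        lambda z: objective_x(_to_bounded(z, lo, hi)),
        z0,
        method="Powell",
        options={"xtol": xtol, "ftol": ftol, "maxiter": max_iterations},
    )
    x_best = _to_bounded(np.atleast_1d(res.x), lo, hi)
    fitted = problem.fixed
    for path, v in zip(paths, x_best):
        fitted = fitted.with_path(path, float(v))
    return CalibrationResult(
        parameters=fitted,
        values=dict(zip(paths, map(float, x_best))),
        mape=float(res.fun),
        n_iterations=int(res.get("nit", 0)),
        n_evaluations=int(res.get("nfev", len(trace))),
        converged=bool(res.success),
        message=str(res.message),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# CSV interchange: columns metric, year, value


def load_observed_series(path: str | Path) -> list[ObservedSeries]:
    df = pd.read_csv(path)
    required = {"metric", "year", "value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"observed-series file {path} must have columns {sorted(required)}"
        )
    out = []
    for metric, group in df.groupby("metric", sort=True):
        group = group.sort_values("year")
        out.append(
            ObservedSeries(
                str(metric),
                tuple(int(y) for y in group["year"]),
                tuple(float(v) for v in group["value"]),
            )
        )
    return out


def save_observed_series(series: Sequence[ObservedSeries], path: str | Path) -> None:
    rows = [
        {"metric": s.metric, "year": y, "value": float(v)}
        for s in sorted(series, key=lambda s: s.metric)
        for y, v in zip(s.years, s.values)
    ]
    pd.DataFrame(rows, columns=["metric", "year", "value"]).to_csv(path, index=False)
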