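"""Run configuration: one YAML file describing a full analysis run.

The defaults reproduce the standard analysis frame: simulation from
1 January 2011 for 20 model years at 8 steps per week, a forecast window
from 2021 to the start of 2031, exhaustive intervention-combination search
for k in {4, 5}, and a 100-draw ±20 % Latin-hypercube sensitivity sweep.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # simulation grid
    start_date: dt.date = dt.date(2011, 1, 1)
    horizon_years: int = 20
    steps_per_week: int = 8
    # forecast window
    window_start: dt.date = dt.date(2021, 1, 1)
    window_end: dt.date = dt.date(2031, 1, 1)
    # paths (None = use the built-in synthetic state / default catalogue)
    catchments_dir: str | None = None
    catalogue_path: str | None = None
    observed_dir: str | None = None
    output_dir: str = "regionsim_output"
    # seeds
    state_seed: int = 1
    lhs_seed: int = 0
    noise_seed: int = 0
    # analysis settings
    n_catchments: int = 10
    k_values: tuple[int, ...] = (4, 5)
    n_lhs_draws: int = 100
    lhs_rel_width: float = 0.20
    observed_noise_cv: float = 0.05
    # calibration settings: (path, lo_mult, hi_mult, init_mult) vs file values
    free_parameters: tuple[tuple[str, float, float, float], ...] = (
        ("distress_onset_rate", 0.5, 1.5, 1.2),
        ("attempt_rate_distressed_untreated", 0.5, 1.5, 0.8),
        ("help_seeking_rate", 0.5, 1.5, 1.2),
    )

    def validate(self) -> None:
        problems = []
        if self.horizon_years < 1:
            problems.append("horizon_years must be >= 1")
        if self.steps_per_week < 1:
            problems.append("steps_per_week must be >= 1")
        if not self.window_start < self.window_end:
            problems.append("window_start must precede window_end")
        if self.window_start < self.start_date:
            problems.append("window_start precedes simulation start")
        if self.n_lhs_draws < 2:
            problems.append("n_lhs_draws must be >= 2")
        if not 0 <= self.lhs_rel_width < 1:
            problems.append("lhs_rel_width must be in [0, 1)")
        if any(k < 1 for k in self.k_values):
            problems.append("k_values must be positive")
        if problems:
            raise ConfigurationError("invalid run config: " + "; ".join(problems))


def load_config(path: str | Path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {p} is not a mapping")
    data.pop("schema_version", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("start_date", "window_start", "window_end"):
        if key in data and not isinstance(data[key], dt.date):
            data[key] = dt.date.fromisoformat(str(data[key]))
    if "k_values" in data:
        data["k_values"] = tuple(int(k) for k in data["k_values"])
    if "free_parameters" in data:
        data["free_parameters"] = tuple(
            (str(a), float(b), float(c), float(d)) for a, b, c, d in data["free_parameters"]
        )
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    for key in ("start_date", "window_start", "window_end"):
        d[key] = d[key].isoformat()
    d["k_values"] = list(d["k_values"])
    d["free_parameters"] = [list(fp) for fp in d["free_parameters"]]
    d["schema_version"] = SCHEMA_VERSION
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
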