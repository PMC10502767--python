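"""Piecewise-constant cohort scenarios.

A scenario describes a closed cohort followed over ``[0, T]`` weeks.
Time is split into intervals on which three quantities are constant:
the outcome hazard in the unexposed ``R0`` (events per person-week),
the exposed:unexposed hazard ratio ``HR`` (so the exposed hazard is
``R1 = HR * R0``), and the rate ``E`` at which unexposed individuals
become exposed (per person-week).  Migration is one-way (unexposed to
exposed) and individuals leave the risk set when the outcome occurs.

Scenarios are read and written as JSON or YAML with keys equal to the
dataclass field names.  Twelve presets covering all combinations of
four hazard-ratio profiles and three new-exposure profiles over three
one-week intervals ship with the package, both as constructors
(:func:`table2_presets`) and as packaged JSON files.
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from .exceptions import ValidationError

__all__ = [
    "PiecewiseScenario",
    "load_scenario",
    "write_scenario",
    "table2_presets",
    "table2_preset",
    "packaged_preset_path",
    "TABLE2_HAZARD_RATIOS",
    "TABLE2_EXPOSURE_RATES",
    "DEFAULT_BASELINE_HAZARD",
    "DEFAULT_INITIAL_UNEXPOSED_PROP",
]

#: Calibration used for the 12 presets: weekly outcome hazard in the
#: unexposed and the initial fraction unexposed.  These are free
#: parameters of the preset family; this pair reproduces the published
#: final-prevalence trajectories of the presets (see docs/methods.md).
DEFAULT_BASELINE_HAZARD = 0.025
DEFAULT_INITIAL_UNEXPOSED_PROP = 0.8

# Hazard-ratio and new-exposure profiles of the 12 presets, in row order:
# four HR profiles (constant protective, constant harmful, waning,
# increasing) crossed with three exposure-uptake profiles (none,
# pulsed, steady).
TABLE2_HAZARD_RATIOS: tuple[tuple[float, float, float], ...] = (
    (0.4, 0.4, 0.4),
    (0.4, 0.4, 0.4),
    (0.4, 0.4, 0.4),
    (2.5, 2.5, 2.5),
    (2.5, 2.5, 2.5),
    (2.5, 2.5, 2.5),
    (0.8, 0.4, 0.2),
    (0.8, 0.4, 0.2),
    (0.8, 0.4, 0.2),
    (1.25, 2.5, 5.0),
    (1.25, 2.5, 5.0),
    (1.25, 2.5, 5.0),
)
TABLE2_EXPOSURE_RATES: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (0.1, 0.5, 0.1),
    (0.1, 0.1, 0.1),
) * 4


def _as_float_tuple(name: str, value) -> tuple[float, ...]:
    try:
        return tuple(float(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: expected a sequence of numbers, got {value!r}") from exc


@dataclass(frozen=True)
class PiecewiseScenario:
    """Full parameterization of a closed-cohort scenario.

    Parameters
    ----------
    interval_bounds
        Strictly increasing times in weeks, first element 0.  Defines
        ``len(interval_bounds) - 1`` intervals.
    baseline_hazard
        Per-interval outcome hazard in the unexposed, events per
        person-week (>= 0).
    hazard_ratio
        Per-interval exposed:unexposed hazard ratio (> 0).
    exposure_rate
        Per-interval rate at which unexposed become exposed, per
        person-week (>= 0).
    initial_size
        Cohort size at t=0 (> 0; defaults to 1, i.e. proportions).
    initial_unexposed_prop
        Fraction of the cohort unexposed at t=0, in [0, 1].
    steps_per_week
        Discretization resolution for numerical integration; each
        interval is split into subintervals of length about
        ``1/steps_per_week`` weeks (boundaries always fall on the grid).
    """

    interval_bounds: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    baseline_hazard: tuple[float, ...] = ()
    hazard_ratio: tuple[float, ...] = ()
    exposure_rate: tuple[float, ...] = ()
    initial_size: float = 1.0
    initial_unexposed_prop: float = field(default=None)  # type: ignore[assignment]
    steps_per_week: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "interval_bounds", _as_float_tuple("interval_bounds", self.interval_bounds))
        for name in ("baseline_hazard", "hazard_ratio", "exposure_rate"):
            object.__setattr__(self, name, _as_float_tuple(name, getattr(self, name)))
        b = self.interval_bounds
        if len(b) < 2:
            raise ValidationError("interval_bounds: need at least two boundaries")
        if b[0] != 0.0:
            raise ValidationError(f"interval_bounds: first element must be 0, got {b[0]}")
        if any(b[i + 1] <= b[i] for i in range(len(b) - 1)):
            raise ValidationError(f"interval_bounds: must be strictly increasing, got {b}")
        k = self.n_intervals
        for name in ("baseline_hazard", "hazard_ratio", "exposure_rate"):
            v = getattr(self, name)
            if len(v) != k:
                raise ValidationError(f"{name}: expected {k} values (one per interval), got {len(v)}")
        if any(v < 0 for v in self.baseline_hazard):
            raise ValidationError(f"baseline_hazard: must be >= 0, got {self.baseline_hazard}")
        if any(v <= 0 for v in self.hazard_ratio):
            raise ValidationError(f"hazard_ratio: must be > 0, got {self.hazard_ratio}")
        if any(v < 0 for v in self.exposure_rate):
            raise ValidationError(f"exposure_rate: must be >= 0, got {self.exposure_rate}")
        if self.initial_unexposed_prop is None:
            raise ValidationError("initial_unexposed_prop: required")
        object.__setattr__(self, "initial_unexposed_prop", float(self.initial_unexposed_prop))
        if not 0.0 <= self.initial_unexposed_prop <= 1.0:
            raise ValidationError(
                f"initial_unexposed_prop: must be in [0, 1], got {self.initial_unexposed_prop}"
            )
        object.__setattr__(self, "initial_size", float(self.initial_size))
        if self.initial_size <= 0:
            raise ValidationError(f"initial_size: must be > 0, got {self.initial_size}")
        if not (isinstance(self.steps_per_week, (int,)) and self.steps_per_week > 0):
            raise ValidationError(f"steps_per_week: must be a positive integer, got {self.steps_per_week!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def n_intervals(self) -> int:
        return len(self.interval_bounds) - 1

    @property
    def duration(self) -> float:
        """Length of the study period in weeks."""
        return self.interval_bounds[-1]

    @property
    def interval_lengths(self) -> tuple[float, ...]:
        b = self.interval_bounds
        return tuple(b[i + 1] - b[i] for i in range(len(b) - 1))

    def exposed_hazard(self, k: int) -> float:
        """Outcome hazard in the exposed on interval ``k``: HR_k * R0_k."""
        return self.hazard_ratio[k] * self.baseline_hazard[k]

    def interval_index(self, t: float) -> int:
        """Index of the interval containing time ``t`` (right-open,
        except the last interval which is closed)."""
        b = self.interval_bounds
        if not b[0] <= t <= b[-1]:
            raise ValidationError(f"time {t} outside study period [0, {b[-1]}]")
        for k in range(self.n_intervals):
            if t < b[k + 1]:
                return k
        return self.n_intervals - 1

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interval_bounds"] = list(d["interval_bounds"])
        for name in ("baseline_hazard", "hazard_ratio", "exposure_rate"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseScenario":
        if not isinstance(d, dict):
            raise ValidationError(f"scenario: expected a mapping, got {type(d).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"scenario: unknown field(s) {sorted(unknown)}; expected {sorted(known)}")
        return cls(**d)


def load_scenario(source: Union[str, os.PathLike, io.TextIOBase, dict]) -> PiecewiseScenario:
    """Load a scenario from a JSON/YAML file path, raw text, open file
    or mapping.

    Strings are treated as paths when a file of that name exists and as
    raw configuration text otherwise.  YAML is a superset of JSON, so a
    single parser handles both.
    """
    if isinstance(source, dict):
        return PiecewiseScenario.from_dict(source)
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, os.PathLike):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = Path(source).read_text() if os.path.exists(source) else source
    else:
        raise ValidationError(f"scenario source: unsupported type {type(source).__name__}")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"scenario: could not parse configuration: {exc}") from exc
    return PiecewiseScenario.from_dict(data)


def write_scenario(scenario: PiecewiseScenario, path: Union[str, os.PathLike], fmt: str | None = None) -> None:
    """Write a scenario to ``path`` as JSON or YAML (inferred from the
    extension when ``fmt`` is not given; JSON if neither applies)."""
    path = Path(path)
    if fmt is None:
        fmt = "yaml" if path.suffix.lower() in {".yml", ".yaml"} else "json"
    if fmt not in {"json", "yaml"}:
        raise ValidationError(f"format: expected 'json' or 'yaml', got {fmt!r}")
    d = scenario.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def table2_presets(
    baseline_hazard_value: float = DEFAULT_BASELINE_HAZARD,
    initial_unexposed_prop: float = DEFAULT_INITIAL_UNEXPOSED_PROP,
    steps_per_week: int = 1000,
) -> list[PiecewiseScenario]:
    """The 12 preset scenarios: three one-week intervals, four
    hazard-ratio profiles crossed with three new-exposure profiles.

    The baseline hazard (shared by all intervals) and initial unexposed
    proportion are calibration parameters of the family; the defaults
    are the package's reference calibration.
    """
    return [
        PiecewiseScenario(
            interval_bounds=(0.0, 1.0, 2.0, 3.0),
            baseline_hazard=(baseline_hazard_value,) * 3,
            hazard_ratio=hr,
            exposure_rate=er,
            initial_size=1.0,
            initial_unexposed_prop=initial_unexposed_prop,
            steps_per_week=steps_per_week,
        )
        for hr, er in zip(TABLE2_HAZARD_RATIOS, TABLE2_EXPOSURE_RATES)
    ]


def table2_preset(row: int, **kwargs) -> PiecewiseScenario:
    """Single preset by 1-based row number (1..12)."""
    if not 1 <= row <= 12:
        raise ValidationError(f"preset row: expected 1..12, got {row}")
    return table2_presets(**kwargs)[row - 1]


def packaged_preset_path(row: int) -> Path:
    """Filesystem path of the packaged JSON file for preset ``row`` (1-based)."""
    if not 1 <= row <= 12:
        raise ValidationError(f"preset row: expected 1..12, got {row}")
    res = resources.files("riskset").joinpath(f"presets/row{row:02d}.json")
    with resources.as_file(res) as p:
        return Path(p)
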