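"""Deterministic integration of the cohort state.

The cohort is tracked as two masses: ``x(t) = N(t) P0(t)`` unexposed
and ``y(t) = N(t) P1(t)`` exposed persons still at risk.  Within each
interval the rates are constant and the state advances by an explicit
(Euler) update on a uniform subgrid:

    x(t+dt) = x(t) (1 - R0 dt - E dt)
    y(t+dt) = y(t) (1 - R1 dt) + E dt x(t)

Deaths remove mass; migration moves the outflow ``E dt x`` from the
unexposed into the exposed compartment, conserving migrants.  Case and
density-control intensities,

    a_i(t) = N P_i R_i           (cases per week in group i)
    b_i(t) = (a_0 + a_1) P_i     (density-sampled controls per week),

are accumulated as left-Riemann sums on the same grid, matching the
explicit scheme.  With 1000 steps per week the scheme agrees with the
exact piecewise-exponential solution to O(dt) (see docs/methods.md).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .scenario import PiecewiseScenario

__all__ = [
    "CohortTrajectory",
    "step_population",
    "integrate_trajectory",
    "final_proportion_unexposed",
]


@dataclass(frozen=True)
class CohortTrajectory:
    """Time-gridded population state and sampling intensities.

    All arrays share the grid's length.  Cumulative counts are
    left-Riemann sums, so ``cum_cases_*[0] == 0`` and the value at the
    last grid point covers the whole study period.
    """

    grid: np.ndarray
    unexposed_mass: np.ndarray            # x(t), persons
    exposed_mass: np.ndarray              # y(t), persons
    case_intensity_unexposed: np.ndarray  # a0(t), cases/week
    case_intensity_exposed: np.ndarray    # a1(t), cases/week
    control_intensity_unexposed: np.ndarray  # b0(t), controls/week
    control_intensity_exposed: np.ndarray    # b1(t), controls/week
    cum_cases_unexposed: np.ndarray       # A0(t)
    cum_cases_exposed: np.ndarray         # A1(t)
    cum_controls_unexposed: np.ndarray    # B0(t)
    cum_controls_exposed: np.ndarray      # B1(t)

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def total_mass(self) -> np.ndarray:
        return self.unexposed_mass + self.exposed_mass

    @property
    def prop_unexposed(self) -> np.ndarray:
        """P0(t) along the grid."""
        return self.unexposed_mass / self.total_mass

    @property
    def prop_exposed(self) -> np.ndarray:
        return self.exposed_mass / self.total_mass

    def left_sum(self, values: np.ndarray) -> float:
        """Left-Riemann sum of a grid function over the study period."""
        return float(np.sum(values[:-1] * np.diff(self.grid)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.grid,
                "x": self.unexposed_mass,
                "y": self.exposed_mass,
                "a0": self.case_intensity_unexposed,
                "a1": self.case_intensity_exposed,
                "b0": self.control_intensity_unexposed,
                "b1": self.control_intensity_exposed,
                "A0": self.cum_cases_unexposed,
                "A1": self.cum_cases_exposed,
                "B0": self.cum_controls_unexposed,
                "B1": self.cum_controls_exposed,
            }
        )

    def to_csv(self, path: Union[str, os.PathLike]) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def step_population(
    unexposed_mass: float,
    exposed_mass: float,
    R0: float,
    R1: float,
    E: float,
    dt: float,
) -> tuple[float, float]:
    """One explicit update of the two compartment masses.

    Raises :class:`DomainError` when the explicit scheme would be
    unstable, i.e. when a compartment could lose more than its whole
    mass in one step ((R0+E)*dt >= 1 or R1*dt >= 1).
    """
    if min(R0, R1, E) < 0:
        raise ValidationError(f"rates must be >= 0, got R0={R0}, R1={R1}, E={E}")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    if (R0 + E) * dt >= 1.0:
        raise DomainError(f"unstable step: (R0 + E)*dt = {(R0 + E) * dt} >= 1; reduce dt")
    if R1 * dt >= 1.0:
        raise DomainError(f"unstable step: R1*dt = {R1 * dt} >= 1; reduce dt")
    x_new = unexposed_mass * (1.0 - R0 * dt - E * dt)
    y_new = exposed_mass * (1.0 - R1 * dt) + E * dt * unexposed_mass
    return x_new, y_new


def _interval_grid(scenario: PiecewiseScenario) -> list[tuple[int, float]]:
    """(number of substeps, dt) per interval; boundaries land on the grid."""
    out = []
    for length in scenario.interval_lengths:
        n_sub = max(1, round(length * scenario.steps_per_week))
        out.append((n_sub, length / n_sub))
    return out


def integrate_trajectory(scenario: PiecewiseScenario) -> CohortTrajectory:
    """Integrate a scenario over the full study period.

    The grid is uniform within each interval with spacing
    ``1/steps_per_week`` (intervals whose length is not a multiple of
    the spacing use the nearest spacing that divides them exactly, so
    every interval boundary is a grid point).  Intensities at a grid
    point use the rates of the interval starting there; cumulative
    counts are left-Riemann sums.
    """
    n_total = sum(n for n, _ in _interval_grid(scenario))
    grid = np.empty(n_total + 1)
    x = np.empty(n_total + 1)
    y = np.empty(n_total + 1)
    a0 = np.empty(n_total + 1)
    a1 = np.empty(n_total + 1)

    grid[0] = 0.0
    x[0] = scenario.initial_size * scenario.initial_unexposed_prop
    y[0] = scenario.initial_size * (1.0 - scenario.initial_unexposed_prop)

    j = 0
    for k, (n_sub, dt) in enumerate(_interval_grid(scenario)):
        R0 = scenario.baseline_hazard[k]
        R1 = scenario.exposed_hazard(k)
        E = scenario.exposure_rate[k]
        t0 = scenario.interval_bounds[k]
        for s in range(n_sub):
            a0[j] = x[j] * R0
            a1[j] = y[j] * R1
            x[j + 1], y[j + 1] = step_population(x[j], y[j], R0, R1, E, dt)
            grid[j + 1] = t0 + (s + 1) * dt
            j += 1
    # intensities at the terminal point use the last interval's rates
    a0[j] = x[j] * scenario.baseline_hazard[-1]
    a1[j] = y[j] * scenario.exposed_hazard(-1)

    total = x + y
    if np.any(total <= 0):
        raise DomainError("cohort extinct: total mass reached 0 inside the study period")
    p0 = x / total
    p1 = y / total
    a_plus = a0 + a1
    b0 = a_plus * p0
    b1 = a_plus * p1

    dts = np.diff(grid)

    def cum(intensity: np.ndarray) -> np.ndarray:
        out = np.empty_like(intensity)
        out[0] = 0.0
        np.cumsum(intensity[:-1] * dts, out=out[1:])
        return out

    return CohortTrajectory(
        grid=grid,
        unexposed_mass=x,
        exposed_mass=y,
        case_intensity_unexposed=a0,
        case_intensity_exposed=a1,
        control_intensity_unexposed=b0,
        control_intensity_exposed=b1,
        cum_cases_unexposed=cum(a0),
        cum_cases_exposed=cum(a1),
        cum_controls_unexposed=cum(b0),
        cum_controls_exposed=cum(b1),
    )


def final_proportion_unexposed(traj: CohortTrajectory) -> float:
    """P0 at the end of the study period."""
    total = traj.unexposed_mass[-1] + traj.exposed_mass[-1]
    if total <= 0:
        raise DomainError("cohort extinct at end of study period")
    return float(traj.unexposed_mass[-1] / total)
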