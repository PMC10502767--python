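"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's Euler/Riemann code
path: compartment masses come from the closed-form solution of the
two-compartment linear ODE (piecewise-constant coefficients), and
integrals over the study period from adaptive quadrature on that
closed form.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

from riskset import PiecewiseScenario, table2_presets


def exact_masses(scenario: PiecewiseScenario, t: float) -> tuple[float, float]:
    """Closed-form (x, y) at time t for the piecewise-linear system
    x' = -(R0+E) x,  y' = -R1 y + E x."""
    x = scenario.initial_size * scenario.initial_unexposed_prop
    y = scenario.initial_size * (1.0 - scenario.initial_unexposed_prop)
    bounds = scenario.interval_bounds
    for k in range(scenario.n_intervals):
        lo, hi = bounds[k], min(bounds[k + 1], t)
        if hi <= lo:
            break
        tau = hi - lo
        r0 = scenario.baseline_hazard[k]
        r1 = scenario.exposed_hazard(k)
        e = scenario.exposure_rate[k]
        lam = r0 + e
        x_new = x * math.exp(-lam * tau)
        if abs(r1 - lam) > 1e-12:
            c = e * x / (r1 - lam)
            y_new = y * math.exp(-r1 * tau) + c * (math.exp(-lam * tau) - math.exp(-r1 * tau))
        else:
            y_new = (y + e * x * tau) * math.exp(-r1 * tau)
        x, y = x_new, y_new
        if hi >= t:
            break
    return x, y


def quad_estimands(scenario: PiecewiseScenario) -> dict:
    """Estimands by adaptive quadrature on the closed-form masses
    (integration split at the interval boundaries)."""

    def rates_at(t: float) -> tuple[float, float]:
        k = scenario.interval_index(min(t, scenario.duration - 1e-12))
        return scenario.baseline_hazard[k], scenario.exposed_hazard(k)

    def piecewise_quad(f) -> float:
        total = 0.0
        b = scenario.interval_bounds
        for k in range(scenario.n_intervals):
            val, _ = quad(f, b[k], b[k + 1], limit=200)
            total += val
        return total

    def x_of(t):
        return exact_masses(scenario, t)[0]

    def y_of(t):
        return exact_masses(scenario, t)[1]

    def a0(t):
        return x_of(t) * rates_at(t)[0]

    def a1(t):
        return y_of(t) * rates_at(t)[1]

    def p0(t):
        x, y = exact_masses(scenario, t)
        return x / (x + y)

    A0 = piecewise_quad(a0)
    A1 = piecewise_quad(a1)
    PT0 = piecewise_quad(x_of)
    PT1 = piecewise_quad(y_of)
    B0 = piecewise_quad(lambda t: (a0(t) + a1(t)) * p0(t))
    B1 = piecewise_quad(lambda t: (a0(t) + a1(t)) * (1 - p0(t)))
    M10 = piecewise_quad(lambda t: a1(t) * p0(t))
    M01 = piecewise_quad(lambda t: a0(t) * (1 - p0(t)))
    xT, yT = exact_masses(scenario, scenario.duration)
    return {
        "rate_ratio": (A1 / PT1) / (A0 / PT0),
        "matched_or": M10 / M01,
        "unmatched_or": (A1 * B0) / (A0 * B1),
        "final_prop_unexposed": xT / (xT + yT),
        "expected_cases": (A0, A1),
        "person_time": (PT0, PT1),
    }


@pytest.fixture(scope="session")
def presets() -> list[PiecewiseScenario]:
    return table2_presets()


@pytest.fixture
def simple_scenario() -> PiecewiseScenario:
    """Two intervals of unequal length with migration and a changing HR."""
    return PiecewiseScenario(
        interval_bounds=(0.0, 1.5, 4.0),
        baseline_hazard=(0.03, 0.05),
        hazard_ratio=(0.5, 2.0),
        exposure_rate=(0.2, 0.05),
        initial_unexposed_prop=0.7,
    )
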