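"""Population estimands of density-sampled case-control designs.

Four quantities summarise what different analyses of a case-control
study converge to in a given scenario:

* ``rate_ratio`` — the person-time outcome-rate ratio
  ``[A1(T)/PT1] / [A0(T)/PT0]``, with ``A_i`` expected cases and
  ``PT_i`` expected person-time in exposure group ``i``;
* ``matched_or`` — the limit of the time-matched (discordant-pair /
  Mantel-Haenszel) odds ratio under 1:m risk-set sampling, computed as
  the ratio of expected exposure-discordant pair masses
  ``M10 / M01`` with ``M_ij = integral of a_i(t) P_j(t) dt``;
* ``unmatched_or`` — the limit of the crude odds ratio when density
  controls are pooled over time, ``A1 B0 / (A0 B1)``;
* ``final_prop_unexposed`` — exposure prevalence at the end of study.

When the hazard ratio is constant the matched OR and the rate ratio
both equal it exactly; when additionally exposure prevalence is
constant over time the unmatched OR coincides too.  Otherwise the
unmatched OR is biased toward the null relative to a constant hazard
ratio, and with both HR and prevalence varying the three quantities
separate — the point these calculations are designed to quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import CohortTrajectory, final_proportion_unexposed, integrate_trajectory
from .exceptions import DomainError
from .scenario import (
    DEFAULT_BASELINE_HAZARD,
    DEFAULT_INITIAL_UNEXPOSED_PROP,
    PiecewiseScenario,
    table2_presets,
)

__all__ = [
    "EstimandSet",
    "rate_ratio",
    "unmatched_or",
    "matched_or",
    "compute_estimands",
    "table2_report",
]


@dataclass(frozen=True)
class EstimandSet:
    """The four summary estimands plus their building blocks."""

    rate_ratio: float
    matched_or: float
    unmatched_or: float
    final_prop_unexposed: float
    person_time: tuple[float, float]       # (PT0, PT1), person-weeks
    expected_cases: tuple[float, float]    # (A0(T), A1(T)), persons
    matched_pair_mass: tuple[float, float]  # (M01, M10) discordant-pair masses

    def to_dict(self) -> dict:
        return {
            "rate_ratio": self.rate_ratio,
            "matched_or": self.matched_or,
            "unmatched_or": self.unmatched_or,
            "final_prop_unexposed": self.final_prop_unexposed,
            "person_time_unexposed": self.person_time[0],
            "person_time_exposed": self.person_time[1],
            "expected_cases_unexposed": self.expected_cases[0],
            "expected_cases_exposed": self.expected_cases[1],
            "discordant_mass_case_unexposed": self.matched_pair_mass[0],
            "discordant_mass_case_exposed": self.matched_pair_mass[1],
        }


def _person_time(traj: CohortTrajectory) -> tuple[float, float]:
    return traj.left_sum(traj.unexposed_mass), traj.left_sum(traj.exposed_mass)


def rate_ratio(traj: CohortTrajectory) -> float:
    """Person-time outcome-rate ratio over the study period."""
    pt0, pt1 = _person_time(traj)
    A0 = traj.cum_cases_unexposed[-1]
    A1 = traj.cum_cases_exposed[-1]
    if pt0 <= 0 or pt1 <= 0:
        raise DomainError(f"rate ratio undefined: person-time (PT0={pt0}, PT1={pt1}) must be positive")
    if A0 <= 0:
        raise DomainError("rate ratio undefined: no expected cases in the unexposed")
    return float((A1 / pt1) / (A0 / pt0))


def unmatched_or(traj: CohortTrajectory) -> float:
    """Crude odds-ratio estimand ``A1 B0 / (A0 B1)`` at end of study."""
    A0 = traj.cum_cases_unexposed[-1]
    A1 = traj.cum_cases_exposed[-1]
    B0 = traj.cum_controls_unexposed[-1]
    B1 = traj.cum_controls_exposed[-1]
    if A0 <= 0 or B1 <= 0:
        raise DomainError(f"unmatched OR undefined: zero denominator count (A0={A0}, B1={B1})")
    return float((A1 * B0) / (A0 * B1))


def matched_or(traj: CohortTrajectory) -> float:
    """Time-matched odds-ratio estimand: ratio of expected
    exposure-discordant pair masses ``M10 / M01``.

    ``M_ij`` integrates ``a_i(t) P_j(t)``: a case in exposure group i
    at t paired with a density control whose probability of being in
    group j is the prevalence ``P_j(t)`` at that instant.  Concordant
    pairs carry no information about the odds ratio and drop out.
    """
    m01, m10 = discordant_pair_masses(traj)
    if m01 <= 0 or m10 <= 0:
        raise DomainError(f"matched OR undefined: zero discordant-pair mass (M01={m01}, M10={m10})")
    return float(m10 / m01)


def discordant_pair_masses(traj: CohortTrajectory) -> tuple[float, float]:
    """(M01, M10): expected mass of case-unexposed/control-exposed and
    case-exposed/control-unexposed pairs under 1:1 risk-set sampling."""
    m01 = traj.left_sum(traj.case_intensity_unexposed * traj.prop_exposed)
    m10 = traj.left_sum(traj.case_intensity_exposed * traj.prop_unexposed)
    return float(m01), float(m10)


def compute_estimands(scenario: PiecewiseScenario) -> EstimandSet:
    """Integrate a scenario and evaluate all estimands from the one
    trajectory."""
    traj = integrate_trajectory(scenario)
    pt = _person_time(traj)
    m01, m10 = discordant_pair_masses(traj)
    return EstimandSet(
        rate_ratio=rate_ratio(traj),
        matched_or=matched_or(traj),
        unmatched_or=unmatched_or(traj),
        final_prop_unexposed=final_proportion_unexposed(traj),
        person_time=pt,
        expected_cases=(
            float(traj.cum_cases_unexposed[-1]),
            float(traj.cum_cases_exposed[-1]),
        ),
        matched_pair_mass=(m01, m10),
    )


def _vec_str(v: tuple[float, ...]) -> str:
    return ", ".join(format(x, "g") for x in v)


def table2_report(
    baseline_hazard_value: float = DEFAULT_BASELINE_HAZARD,
    initial_unexposed_prop: float = DEFAULT_INITIAL_UNEXPOSED_PROP,
    steps_per_week: int = 1000,
) -> pd.DataFrame:
    """Estimand table for the 12 preset scenarios.

    Returns one row per preset with the hazard-ratio and new-exposure
    profiles, the four estimands at full precision, and 2-decimal
    roundings (round-half-even) for display.
    """
    rows = []
    for i, sc in enumerate(
        table2_presets(baseline_hazard_value, initial_unexposed_prop, steps_per_week), start=1
    ):
        est = compute_estimands(sc)
        rows.append(
            {
                "row": i,
                "hazard_ratio": _vec_str(sc.hazard_ratio),
                "exposure_rate": _vec_str(sc.exposure_rate),
                "rate_ratio": est.rate_ratio,
                "matched_or": est.matched_or,
                "unmatched_or": est.unmatched_or,
                "final_prop_unexposed": est.final_prop_unexposed,
            }
        )
    df = pd.DataFrame(rows).set_index("row")
    for col in ("rate_ratio", "matched_or", "unmatched_or", "final_prop_unexposed"):
        df[col + "_2dp"] = df[col].round(2)
    return df
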