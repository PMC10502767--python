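"""Closed-cohort 2x2 algebra.

For a closed cohort cross-classified by exposure and outcome over a
study period,

              exposed   unexposed
    event        a          b
    no event     c          d

the outcome odds ratio ``ad/bc`` equals the exposure odds ratio, and
the exposure odds of cases relative to the *whole cohort* equals the
risk ratio ``[a/(a+c)] / [b/(b+d)]``.  Consequently the sample OR of a
case-control study targets different population quantities depending
on where controls are drawn: from non-cases (``ad/bc``, the
"cumulative"/exclusive design) or from the full cohort (the risk
ratio, the case-cohort design).

No continuity corrections are applied anywhere: these identities
concern population parameters, not small-sample estimates, so zero
cells raise :class:`DomainError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .exceptions import DomainError, UnsupportedDesignError, ValidationError
from .scenario import PiecewiseScenario

__all__ = [
    "TwoByTwo",
    "ControlDraw",
    "odds_ratio",
    "risk_ratio",
    "sample_or_from_controls",
    "expected_two_by_two",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts for a closed cohort."""

    exposed_cases: float      # a
    unexposed_cases: float    # b
    exposed_noncases: float   # c
    unexposed_noncases: float  # d

    def __post_init__(self) -> None:
        for name in ("exposed_cases", "unexposed_cases", "exposed_noncases", "unexposed_noncases"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: counts must be >= 0, got {getattr(self, name)}")

    @property
    def a(self) -> float:
        return self.exposed_cases

    @property
    def b(self) -> float:
        return self.unexposed_cases

    @property
    def c(self) -> float:
        return self.exposed_noncases

    @property
    def d(self) -> float:
        return self.unexposed_noncases

    def transpose(self) -> "TwoByTwo":
        """Swap the roles of exposure and outcome (a stays, b and c swap)."""
        return TwoByTwo(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class ControlDraw:
    """Controls sampled for the cases of a :class:`TwoByTwo` cohort.

    ``source`` records where they came from: ``"noncases"`` (counts
    e = exposed, f = unexposed, drawn from c and d) or
    ``"whole_cohort"`` (g, h drawn from a+c and b+d at baseline).
    """

    exposed_controls: float
    unexposed_controls: float
    source: Literal["noncases", "whole_cohort"]

    def __post_init__(self) -> None:
        if self.exposed_controls < 0 or self.unexposed_controls < 0:
            raise ValidationError("control counts must be >= 0")
        if self.source not in ("noncases", "whole_cohort"):
            raise ValidationError(f"source: expected 'noncases' or 'whole_cohort', got {self.source!r}")


def odds_ratio(t: TwoByTwo) -> float:
    """Population odds ratio ``ad/bc`` (outcome OR = exposure OR)."""
    if t.b * t.c <= 0:
        raise DomainError(f"odds ratio undefined: zero cell in denominator (b={t.b}, c={t.c})")
    return (t.a * t.d) / (t.b * t.c)


def risk_ratio(t: TwoByTwo) -> float:
    """Risk ratio ``[a/(a+c)] / [b/(b+d)]``."""
    if t.a + t.c <= 0 or t.b + t.d <= 0:
        raise DomainError("risk ratio undefined: empty exposure group")
    if t.b <= 0:
        raise DomainError("risk ratio undefined: zero risk in the unexposed")
    return (t.a / (t.a + t.c)) / (t.b / (t.b + t.d))


def sample_or_from_controls(cases: tuple[float, float], controls: ControlDraw) -> float:
    """Exposure odds of cases against a control draw.

    ``cases`` is (a, b) = (exposed, unexposed) case counts.  For
    noncase controls the result ``a f / (b e)`` is consistent for the
    population OR ``ad/bc``; for whole-cohort controls ``(a/b)/(g/h)``
    is consistent for the risk ratio.  Sampling fractions cancel.
    """
    a, b = cases
    if a < 0 or b < 0:
        raise ValidationError(f"case counts must be >= 0, got {cases}")
    e_or_g = controls.exposed_controls
    f_or_h = controls.unexposed_controls
    if b <= 0 or e_or_g <= 0:
        raise DomainError(
            f"sample OR undefined: zero denominator (unexposed cases={b}, exposed controls={e_or_g})"
        )
    if f_or_h <= 0:
        raise DomainError("sample OR undefined: no unexposed controls")
    return (a * f_or_h) / (b * e_or_g)


def expected_two_by_two(scenario: PiecewiseScenario) -> TwoByTwo:
    """Expected closed-cohort 2x2 for a fixed-exposure scenario.

    Only defined when exposure is a fixed baseline attribute
    (all exposure rates zero); with migration the cohort cannot be
    cross-classified by a single exposure value.
    """
    if any(e > 0 for e in scenario.exposure_rate):
        raise UnsupportedDesignError(
            "closed-cohort 2x2 requires fixed exposure (all exposure rates zero); "
            f"got exposure_rate={scenario.exposure_rate}"
        )
    from .dynamics import integrate_trajectory  # local import to avoid cycle

    traj = integrate_trajectory(scenario)
    return TwoByTwo(
        exposed_cases=float(traj.cum_cases_exposed[-1]),
        unexposed_cases=float(traj.cum_cases_unexposed[-1]),
        exposed_noncases=float(traj.exposed_mass[-1]),
        unexposed_noncases=float(traj.unexposed_mass[-1]),
    )
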