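"""Individual-level Monte Carlo cohort simulation and control sampling.

This is the stochastic twin of the deterministic integrator: each
individual starts unexposed with probability ``P0(0)`` and, while
unexposed and event-free, faces competing piecewise-exponential risks
of becoming exposed (rate ``E``) and of the outcome (rate ``R0``);
after switching, the outcome hazard becomes ``R1 = HR * R0``.  Cases
are then sampled together with controls under four designs:

``risk_set``
    for each case at time t, m controls drawn uniformly without
    replacement from everyone still event-free at t (future cases are
    eligible and one person may serve several cases), exposure
    recorded as of t, matched-set id kept;
``unmatched_density``
    the same draws with the matching discarded;
``cumulative``
    controls drawn from those event-free at the end of study;
``case_cohort``
    controls drawn from the whole baseline cohort.

The last two treat exposure as a fixed attribute and therefore require
a scenario without exposure migration.  Analysing the samples with the
Mantel-Haenszel matched OR versus the crude pooled OR, and comparing
against the deterministic estimands, verifies empirically which design
is consistent for which population quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .contingency import expected_two_by_two, odds_ratio, risk_ratio
from .estimands import compute_estimands
from .exceptions import DomainError, UnsupportedDesignError, ValidationError
from .scenario import PiecewiseScenario

__all__ = [
    "IndividualHistory",
    "CohortHistories",
    "CaseControlSample",
    "sample_piecewise_exponential",
    "simulate_cohort",
    "draw_case_control",
    "crude_or",
    "mantel_haenszel_or",
    "convergence_report",
    "DESIGNS",
]

DESIGNS = ("risk_set", "unmatched_density", "case_cohort", "cumulative")

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_piecewise_exponential(
    rates: Sequence[float],
    bounds: Sequence[float],
    rng: np.random.Generator,
    size: Optional[int] = None,
    start_time: Union[float, np.ndarray] = 0.0,
) -> Union[float, np.ndarray]:
    """Draw event times from a piecewise-constant hazard, truncated at
    the last bound.

    Inverse-CDF sampling: a unit-exponential target is compared with
    the cumulative hazard accrued across intervals from ``start_time``
    onward.  Individuals whose target is never reached survive past
    the end of follow-up and are returned as ``inf``.  ``start_time``
    may be an array (one entry per draw); an infinite start yields an
    infinite time.

    With ``size=None`` and scalar ``start_time`` a single float is
    returned, otherwise an array.
    """
    rates = np.asarray(rates, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if rates.ndim != 1 or bounds.ndim != 1 or len(bounds) != len(rates) + 1:
        raise ValidationError("rates/bounds: expected K rates and K+1 bounds")
    if np.any(rates < 0):
        raise ValidationError(f"rates: must be >= 0, got {rates}")
    if np.any(np.diff(bounds) <= 0):
        raise ValidationError(f"bounds: must be strictly increasing, got {bounds}")

    scalar = size is None and np.ndim(start_time) == 0
    start = np.atleast_1d(np.asarray(start_time, dtype=float))
    n = size if size is not None else len(start)
    start = np.broadcast_to(start, (n,))

    seg_start = np.maximum(bounds[:-1][None, :], start[:, None])
    seg_len = np.clip(bounds[1:][None, :] - seg_start, 0.0, None)
    cum_h = np.cumsum(rates[None, :] * seg_len, axis=1)

    target = rng.exponential(size=n)
    crossed = cum_h >= target[:, None]
    reached = crossed.any(axis=1)
    k = np.argmax(crossed, axis=1)
    prev = np.where(k > 0, np.take_along_axis(cum_h, np.maximum(k - 1, 0)[:, None], 1)[:, 0], 0.0)
    r_k = rates[k]
    t0 = np.take_along_axis(seg_start, k[:, None], 1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        times = np.where(r_k > 0, t0 + (target - prev) / np.where(r_k > 0, r_k, 1.0), t0)
    times = np.where(reached, times, np.inf)
    return float(times[0]) if scalar else times


class IndividualHistory(NamedTuple):
    """One simulated follow-up record; ``None`` marks an event that
    never happened during follow-up."""

    initial_exposure: bool
    exposure_switch_time: Optional[float]
    event_time: Optional[float]


@dataclass(frozen=True)
class CohortHistories:
    """Array-backed collection of individual histories.

    ``switch_time``/``event_time`` use ``inf`` for "did not happen by
    the end of follow-up"; indexing returns an
    :class:`IndividualHistory` with ``None`` instead.
    """

    scenario: PiecewiseScenario
    initial_exposed: np.ndarray  # bool
    switch_time: np.ndarray      # weeks; inf = never switched while at risk
    event_time: np.ndarray       # weeks; inf = no event by end of study

    def __len__(self) -> int:
        return len(self.event_time)

    def __getitem__(self, i: int) -> IndividualHistory:
        sw = self.switch_time[i]
        ev = self.event_time[i]
        return IndividualHistory(
            bool(self.initial_exposed[i]),
            None if np.isinf(sw) else float(sw),
            None if np.isinf(ev) else float(ev),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def duration(self) -> float:
        return self.scenario.duration

    @property
    def has_migration(self) -> bool:
        return any(e > 0 for e in self.scenario.exposure_rate)

    def exposed_at(self, t: Union[float, np.ndarray]) -> np.ndarray:
        """Exposure status of every individual at time(s) ``t``."""
        return self.initial_exposed | (self.switch_time <= t)

    def at_risk_at(self, t: float) -> np.ndarray:
        """Event-free (still at risk) indicator at time ``t``."""
        return self.event_time > t

    def counts_at(self, t: float) -> tuple[int, int]:
        """(unexposed, exposed) persons at risk at time ``t``."""
        risk = self.at_risk_at(t)
        exp = self.exposed_at(t)
        return int(np.sum(risk & ~exp)), int(np.sum(risk & exp))


def simulate_cohort(scenario: PiecewiseScenario, n: int, seed: SeedLike) -> CohortHistories:
    """Simulate ``n`` independent individual histories under a scenario.

    Draws are made stage-wise (initial exposure; switch time; event
    time while unexposed; event time while/after exposed) from
    independent generators spawned off one seed, so the result is
    reproducible and independent of any iteration order.  Exact ties
    between a switch and an event resolve in favour of the event.
    """
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_init, rng_switch, rng_ev0, rng_ev1 = map(np.random.default_rng, ss.spawn(4))

    bounds = np.asarray(scenario.interval_bounds)
    r0 = np.asarray(scenario.baseline_hazard)
    r1 = r0 * np.asarray(scenario.hazard_ratio)
    e_rate = np.asarray(scenario.exposure_rate)

    initial_exposed = rng_init.random(n) >= scenario.initial_unexposed_prop
    t_switch = sample_piecewise_exponential(e_rate, bounds, rng_switch, size=n)
    t_event0 = sample_piecewise_exponential(r0, bounds, rng_ev0, size=n)

    # clock for the exposed-phase hazard: 0 for the initially exposed,
    # the switch time for migrants, inf (=> no draw) otherwise
    exposed_from = np.where(initial_exposed, 0.0, t_switch)
    t_event1 = sample_piecewise_exponential(r1, bounds, rng_ev1, size=n, start_time=exposed_from)

    died_unexposed = ~initial_exposed & (t_event0 <= t_switch)
    event_time = np.where(initial_exposed, t_event1, np.where(died_unexposed, t_event0, t_event1))
    switched = ~initial_exposed & (t_switch < t_event0) & np.isfinite(t_switch)
    switch_time = np.where(switched, t_switch, np.inf)

    return CohortHistories(
        scenario=scenario,
        initial_exposed=initial_exposed,
        switch_time=switch_time,
        event_time=event_time,
    )


@dataclass(frozen=True)
class CaseControlSample:
    """A drawn case-control sample (one entry per sampled subject).

    ``matched_set`` is -1 where no matching applies.  ``subject`` is
    the index into the source cohort; a subject may appear several
    times (as control for several cases, or as both control and later
    case) under density designs.
    """

    design: str
    subject: np.ndarray      # int
    is_case: np.ndarray      # bool
    exposed: np.ndarray      # bool, status at sampling time
    time: np.ndarray         # sampling time, weeks
    matched_set: np.ndarray  # int, -1 = absent

    def __len__(self) -> int:
        return len(self.subject)

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.is_case))

    def cells(self) -> tuple[int, int, int, int]:
        """Pooled counts (exposed cases, unexposed cases, exposed
        controls, unexposed controls)."""
        case, exp = self.is_case, self.exposed
        return (
            int(np.sum(case & exp)),
            int(np.sum(case & ~exp)),
            int(np.sum(~case & exp)),
            int(np.sum(~case & ~exp)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "role": np.where(self.is_case, "case", "control"),
                "exposed": self.exposed.astype(int),
                "time": self.time,
                "matched_set": self.matched_set,
                "design": self.design,
            }
        )


def _normalize_design(design: str) -> str:
    d = design.replace("-", "_")
    if d not in DESIGNS:
        raise ValidationError(f"design: expected one of {DESIGNS}, got {design!r}")
    return d


def _distinct_uniform(rng: np.random.Generator, low: int, high: int, m: int) -> np.ndarray:
    """m distinct uniform integers in [low, high); m << high - low."""
    while True:
        draw = rng.integers(low, high, size=m)
        if len(np.unique(draw)) == m:
            return draw


def draw_case_control(
    histories: CohortHistories,
    design: str,
    controls_per_case: int = 1,
    seed: SeedLike = 0,
) -> CaseControlSample:
    """Sample cases and controls from a simulated cohort under one of
    the four designs (see module docstring)."""
    design = _normalize_design(design)
    m = int(controls_per_case)
    if m < 1:
        raise ValidationError(f"controls_per_case: must be >= 1, got {controls_per_case}")
    rng = _as_rng(seed)

    ev = histories.event_time
    n = len(ev)
    case_ids = np.flatnonzero(np.isfinite(ev))
    if len(case_ids) == 0:
        raise DomainError("no cases in the cohort; nothing to sample")

    if design in ("risk_set", "unmatched_density"):
        order = np.argsort(ev, kind="stable")  # cases first, ascending in time
        k = len(case_ids)
        case_pos = np.arange(k)
        case_sorted = order[:k]
        case_times = ev[case_sorted]
        if n - 1 - (k - 1) < m:  # smallest risk set is for the last case
            raise DomainError(
                f"risk set too small: last case leaves {n - k} at risk, need {m} controls"
            )
        if m == 1:
            ctrl_pos = rng.integers(case_pos + 1, n)
        else:
            ctrl_pos = np.concatenate(
                [_distinct_uniform(rng, p + 1, n, m) for p in case_pos]
            )
        ctrl_ids = order[ctrl_pos]
        ctrl_times = np.repeat(case_times, m)
        set_ids = np.arange(k)
        sample_sets = (
            np.concatenate([set_ids, np.repeat(set_ids, m)])
            if design == "risk_set"
            else np.full(k + k * m, -1)
        )
        subject = np.concatenate([case_sorted, ctrl_ids])
        is_case = np.concatenate([np.ones(k, bool), np.zeros(k * m, bool)])
        times = np.concatenate([case_times, ctrl_times])
        exposed = histories.initial_exposed[subject] | (histories.switch_time[subject] <= times)
        return CaseControlSample(design, subject, is_case, exposed, times, sample_sets)

    if design in ("case_cohort", "cumulative") and histories.has_migration:
        raise UnsupportedDesignError(
            f"{design} design requires fixed exposure (all exposure rates zero); "
            "this cohort has exposure migration"
        )

    k = len(case_ids)
    n_controls = k * m
    if design == "cumulative":
        pool = np.flatnonzero(np.isinf(ev))  # event-free at end of study
        t_ctrl = histories.duration
    else:  # case_cohort: whole cohort at baseline, exposure is fixed
        pool = np.arange(n)
        t_ctrl = 0.0
    if len(pool) < n_controls:
        raise DomainError(
            f"{design}: control pool has {len(pool)} members, need {n_controls}"
        )
    ctrl_ids = rng.choice(pool, size=n_controls, replace=False)
    subject = np.concatenate([case_ids, ctrl_ids])
    is_case = np.concatenate([np.ones(k, bool), np.zeros(n_controls, bool)])
    times = np.concatenate([ev[case_ids], np.full(n_controls, t_ctrl)])
    # exposure is a fixed attribute here (no migration), so status at
    # any time equals the baseline status
    exposed = histories.initial_exposed[subject]
    return CaseControlSample(design, subject, is_case, exposed, times, np.full(len(subject), -1))


def crude_or(sample: CaseControlSample) -> float:
    """Pooled (time-ignoring) sample odds ratio."""
    a, b, e, f = sample.cells()
    if b == 0 or e == 0:
        raise DomainError(f"crude OR undefined: zero cell (unexposed cases={b}, exposed controls={e})")
    if a == 0 or f == 0:
        raise DomainError(f"crude OR undefined: zero cell (exposed cases={a}, unexposed controls={f})")
    return (a * f) / (b * e)


def mantel_haenszel_or(sample: CaseControlSample) -> float:
    """Mantel-Haenszel odds ratio over matched sets.

    With one case and one control per set this reduces to the ratio of
    exposure-discordant pair counts (case-exposed : control-exposed).
    """
    if np.all(sample.matched_set < 0):
        raise DomainError("Mantel-Haenszel OR requires matched sets; this sample has none")
    sid = sample.matched_set
    n_sets = int(sid.max()) + 1
    count = lambda mask: np.bincount(sid[mask & (sid >= 0)], minlength=n_sets)
    a_k = count(sample.is_case & sample.exposed)
    b_k = count(sample.is_case & ~sample.exposed)
    c_k = count(~sample.is_case & sample.exposed)
    d_k = count(~sample.is_case & ~sample.exposed)
    n_k = a_k + b_k + c_k + d_k
    num = float(np.sum(a_k * d_k / n_k))
    den = float(np.sum(b_k * c_k / n_k))
    if num == 0.0 or den == 0.0:
        n_up = int(np.sum((a_k * d_k) > 0))
        n_dn = int(np.sum((b_k * c_k) > 0))
        raise DomainError(
            "Mantel-Haenszel OR undefined: need exposure-discordant sets in both directions "
            f"(case-exposed discordant: {n_up}, control-exposed discordant: {n_dn})"
        )
    return num / den


_DESIGN_ESTIMATOR = {
    "risk_set": mantel_haenszel_or,
    "unmatched_density": crude_or,
    "cumulative": crude_or,
    "case_cohort": crude_or,
}


def _design_target(scenario: PiecewiseScenario, design: str) -> tuple[str, float]:
    est = compute_estimands(scenario)
    if design == "risk_set":
        return "matched_or", est.matched_or
    if design == "unmatched_density":
        return "unmatched_or", est.unmatched_or
    table = expected_two_by_two(scenario)
    if design == "cumulative":
        return "population_or", odds_ratio(table)
    return "risk_ratio", risk_ratio(table)


def convergence_report(
    scenario: PiecewiseScenario,
    designs: Sequence[str],
    n: int,
    replicates: int,
    seed: SeedLike,
    controls_per_case: int = 1,
) -> pd.DataFrame:
    """Replicate cohorts, sample under each design, and compare the
    sample ORs with the deterministic estimand each design targets.

    Returns one row per design: the target name and value, the mean
    and standard error of the log sample OR across replicates, and the
    z-score of the gap.  Cohorts are shared across designs within a
    replicate; everything is reproducible from ``seed``.
    """
    designs = [_normalize_design(d) for d in designs]
    if replicates < 1:
        raise ValidationError(f"replicates: must be >= 1, got {replicates}")
    targets = {d: _design_target(scenario, d) for d in designs}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    logs = {d: [] for d in designs}
    for child in ss.spawn(replicates):
        streams = child.spawn(1 + len(designs))
        cohort = simulate_cohort(scenario, n, streams[0])
        for d, stream in zip(designs, streams[1:]):
            sample = draw_case_control(cohort, d, controls_per_case, np.random.default_rng(stream))
            logs[d].append(np.log(_DESIGN_ESTIMATOR[d](sample)))
    rows = []
    for d in designs:
        arr = np.asarray(logs[d])
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        name, target = targets[d]
        z = (mean - np.log(target)) / se if se > 0 else float("nan")
        rows.append(
            {
                "design": d,
                "target_name": name,
                "target": target,
                "mean_log_or": mean,
                "se_log_or": se,
                "mean_or": float(np.exp(mean)),
                "z": float(z),
                "n": n,
                "replicates": replicates,
                "controls_per_case": controls_per_case,
            }
        )
    return pd.DataFrame(rows)
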