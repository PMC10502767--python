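"""Monte Carlo machinery: event-time draws, cohort simulation, and the
four control-sampling designs."""

import numpy as np
import pytest
from scipy import stats

from conftest import exact_masses
from riskset import (
    CaseControlSample,
    DomainError,
    PiecewiseScenario,
    UnsupportedDesignError,
    compute_estimands,
    convergence_report,
    crude_or,
    draw_case_control,
    mantel_haenszel_or,
    sample_piecewise_exponential,
    simulate_cohort,
    table2_preset,
)

BOUNDS = (0.0, 1.0, 2.0, 3.0)


class TestPiecewiseExponential:
    def test_zero_rates_never_fire(self):
        rng = np.random.default_rng(0)
        t = sample_piecewise_exponential((0.0,) * 3, BOUNDS, rng, size=1000)
        assert np.all(np.isinf(t))

    def test_constant_rate_median(self):
        rng = np.random.default_rng(1)
        r = 1.5  # median ln2/r ~ 0.46 < 3
        t = sample_piecewise_exponential((r,) * 3, BOUNDS, rng, size=100_000)
        finite = t[np.isfinite(t)]
        assert np.median(finite) == pytest.approx(np.log(2) / r, abs=0.01)

    def test_empirical_cdf_matches_closed_form(self):
        """Kolmogorov distance to the analytic piecewise CDF < 0.01 at 1e5 draws."""
        rates = np.array([0.3, 1.0, 0.1])
        rng = np.random.default_rng(2)
        n = 100_000
        t = sample_piecewise_exponential(rates, BOUNDS, rng, size=n)
        t = np.where(np.isinf(t), 4.0, t)  # censored past T -> point mass

        def cdf(x):
            x = np.asarray(x, float)
            cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(BOUNDS))])
            h = np.zeros_like(x)
            for k in range(3):
                h += np.clip(x - BOUNDS[k], 0, BOUNDS[k + 1] - BOUNDS[k]) * rates[k]
            return 1 - np.exp(-h)

        grid = np.linspace(0.0, 2.999, 500)
        emp = np.searchsorted(np.sort(t), grid, side="right") / n
        assert np.max(np.abs(emp - cdf(grid))) < 0.01

    def test_vector_start_times(self):
        rng = np.random.default_rng(3)
        start = np.array([0.0, 2.5, np.inf])
        t = sample_piecewise_exponential((5.0,) * 3, BOUNDS, rng, size=3, start_time=start)
        assert t[0] >= 0.0
        assert t[1] >= 2.5 or np.isinf(t[1])
        assert np.isinf(t[2])

    def test_scalar_call_returns_float(self):
        rng = np.random.default_rng(4)
        t = sample_piecewise_exponential((10.0,) * 3, BOUNDS, rng)
        assert isinstance(t, float)


class TestSimulateCohort:
    def test_seed_determinism(self):
        sc = table2_preset(2)
        a = simulate_cohort(sc, 5000, 99)
        b = simulate_cohort(sc, 5000, 99)
        assert np.array_equal(a.event_time, b.event_time)
        assert np.array_equal(a.switch_time, b.switch_time)
        assert np.array_equal(a.initial_exposed, b.initial_exposed)

    def test_history_records_are_consistent(self):
        sc = table2_preset(2)
        coh = simulate_cohort(sc, 20_000, 5)
        # a recorded switch happens strictly before the event
        both = np.isfinite(coh.switch_time) & np.isfinite(coh.event_time)
        assert np.all(coh.switch_time[both] < coh.event_time[both])
        assert not np.any(coh.initial_exposed & np.isfinite(coh.switch_time))
        finite_ev = coh.event_time[np.isfinite(coh.event_time)]
        assert np.all((finite_ev >= 0) & (finite_ev <= sc.duration))
        # sequence protocol: absent times become None
        h = coh[0]
        assert isinstance(h.initial_exposure, bool)

    def test_final_prevalence_matches_deterministic(self):
        """Empirical final proportion unexposed within 3 binomial SE of
        the integrator's value."""
        sc = table2_preset(1)
        n = 100_000
        coh = simulate_cohort(sc, n, 7)
        u, e = coh.counts_at(sc.duration - 1e-9)
        p_hat = u / (u + e)
        p_ref = compute_estimands(sc).final_prop_unexposed
        se = np.sqrt(p_ref * (1 - p_ref) / (u + e))
        assert abs(p_hat - p_ref) < 3 * se

    def test_mean_trajectory_tracks_closed_form(self):
        """Group masses along the grid within 2% (sup-norm, relative)
        of the deterministic trajectory at n = 1e5."""
        sc = table2_preset(2)
        n = 100_000
        coh = simulate_cohort(sc, n, 11)
        for t in np.linspace(0.0, 2.99, 13):
            x_ref, y_ref = exact_masses(sc, t)
            u, e = coh.counts_at(t)
            assert abs(u / n - x_ref) / x_ref < 0.02
            assert abs(e / n - y_ref) / y_ref < 0.02

    def test_null_hr_event_rate_independent_of_exposure_path(self):
        """With HR = 1, final case status is independent of initial
        exposure (chi-square on the 2x2, alpha = 1e-3)."""
        sc = PiecewiseScenario(
            interval_bounds=BOUNDS,
            baseline_hazard=(0.05,) * 3,
            hazard_ratio=(1.0,) * 3,
            exposure_rate=(0.0,) * 3,
            initial_unexposed_prop=0.6,
        )
        coh = simulate_cohort(sc, 50_000, 13)
        case = np.isfinite(coh.event_time)
        table = [
            [np.sum(case & coh.initial_exposed), np.sum(case & ~coh.initial_exposed)],
            [np.sum(~case & coh.initial_exposed), np.sum(~case & ~coh.initial_exposed)],
        ]
        assert stats.chi2_contingency(table).pvalue > 1e-3


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(table2_preset(2), 30_000, 17)


@pytest.fixture(scope="module")
def fixed_cohort():
    return simulate_cohort(table2_preset(4), 30_000, 19)


class TestDrawCaseControl:
    @pytest.mark.parametrize("m", [1, 3])
    def test_risk_set_structure(self, cohort, m):
        s = draw_case_control(cohort, "risk_set", controls_per_case=m, seed=1)
        sets, counts = np.unique(s.matched_set, return_counts=True)
        assert np.all(sets >= 0)
        assert np.all(counts == 1 + m)
        # each set: one case, m controls; control time equals case time
        for sid in sets[:20]:
            mask = s.matched_set == sid
            assert s.is_case[mask].sum() == 1
            assert len(np.unique(s.time[mask])) == 1

    def test_controls_event_free_at_sampling_time(self, cohort):
        s = draw_case_control(cohort, "risk_set", seed=2)
        ctrl = ~s.is_case
        assert np.all(cohort.event_time[s.subject[ctrl]] > s.time[ctrl])

    def test_unmatched_density_has_no_sets(self, cohort):
        s = draw_case_control(cohort, "unmatched_density", seed=3)
        assert np.all(s.matched_set == -1)

    def test_control_exposure_prevalence_tracks_trajectory(self, cohort):
        """Risk-set control exposure at case times follows P1(t) of the
        deterministic trajectory (pooled 3-SE check)."""
        s = draw_case_control(cohort, "risk_set", seed=4)
        ctrl = ~s.is_case
        sc = cohort.scenario
        p1 = np.array([1 - exact_masses(sc, t)[0] / sum(exact_masses(sc, t)) for t in s.time[ctrl]])
        n = ctrl.sum()
        expected = p1.mean()
        se = np.sqrt(np.mean(p1 * (1 - p1)) / n)
        assert abs(s.exposed[ctrl].mean() - expected) < 3 * se

    def test_density_designs_allow_migration_cohorts(self, cohort):
        for design in ("risk_set", "unmatched_density"):
            draw_case_control(cohort, design, seed=5)

    def test_case_cohort_requires_fixed_exposure(self, cohort, fixed_cohort):
        with pytest.raises(UnsupportedDesignError):
            draw_case_control(cohort, "case_cohort", seed=6)
        s = draw_case_control(fixed_cohort, "case_cohort", seed=6)
        assert np.all(s.time[~s.is_case] == 0.0)

    def test_cumulative_requires_fixed_exposure(self, cohort, fixed_cohort):
        with pytest.raises(UnsupportedDesignError):
            draw_case_control(cohort, "cumulative", seed=7)
        s = draw_case_control(fixed_cohort, "cumulative", seed=7)
        ctrl = ~s.is_case
        assert np.all(np.isinf(fixed_cohort.event_time[s.subject[ctrl]]))

    def test_no_cases_raises(self):
        sc = PiecewiseScenario(
            interval_bounds=BOUNDS,
            baseline_hazard=(0.0,) * 3,
            hazard_ratio=(1.0,) * 3,
            exposure_rate=(0.0,) * 3,
            initial_unexposed_prop=0.8,
        )
        coh = simulate_cohort(sc, 100, 1)
        with pytest.raises(DomainError, match="no cases"):
            draw_case_control(coh, "cumulative", seed=1)


def _hand_sample(n_case_exposed_discordant, n_control_exposed_discordant, n_concordant=4):
    """Build a 1:1 matched sample with the given discordant-pair counts."""
    sets = []
    k = 0
    rows = []  # (is_case, exposed, set)
    for _ in range(n_case_exposed_discordant):
        rows += [(True, True, k), (False, False, k)]
        k += 1
    for _ in range(n_control_exposed_discordant):
        rows += [(True, False, k), (False, True, k)]
        k += 1
    for _ in range(n_concordant):
        rows += [(True, True, k), (False, True, k)]
        k += 1
    is_case, exposed, sid = (np.array(v) for v in zip(*rows))
    n = len(rows)
    return CaseControlSample(
        "risk_set", np.arange(n), is_case, exposed, np.zeros(n), sid
    )


class TestOrEstimators:
    def test_crude_or_cells(self):
        s = CaseControlSample(
            "unmatched_density",
            np.arange(6),
            np.array([True, True, True, False, False, False]),
            np.array([True, True, False, True, False, False]),
            np.zeros(6),
            np.full(6, -1),
        )
        assert s.cells() == (2, 1, 1, 2)
        assert crude_or(s) == pytest.approx(4.0)

    def test_crude_or_ignores_matched_ids(self):
        a = _hand_sample(10, 5)
        relabeled = CaseControlSample(
            a.design, a.subject, a.is_case, a.exposed, a.time, a.matched_set[::-1].copy()
        )
        assert crude_or(a) == crude_or(relabeled)

    def test_mh_or_discordant_ratio(self):
        assert mantel_haenszel_or(_hand_sample(10, 5)) == pytest.approx(2.0)

    def test_mh_or_all_concordant_raises(self):
        with pytest.raises(DomainError, match="discordant"):
            mantel_haenszel_or(_hand_sample(0, 0, n_concordant=8))

    def test_mh_or_requires_matched_sets(self):
        s = _hand_sample(10, 5)
        unmatched = CaseControlSample(
            "unmatched_density", s.subject, s.is_case, s.exposed, s.time, np.full(len(s), -1)
        )
        with pytest.raises(DomainError, match="matched"):
            mantel_haenszel_or(unmatched)

    def test_zero_cell_crude_or_raises(self):
        z = CaseControlSample(
            "unmatched_density",
            np.arange(4),
            np.array([True, True, False, False]),
            np.array([True, True, False, False]),
            np.zeros(4),
            np.full(4, -1),
        )
        with pytest.raises(DomainError):
            crude_or(z)


class TestConvergenceReport:
    def test_report_is_seed_deterministic(self):
        sc = table2_preset(2)
        a = convergence_report(sc, ["risk_set"], 5000, 3, seed=21)
        b = convergence_report(sc, ["risk_set"], 5000, 3, seed=21)
        assert a.equals(b)

    def test_designs_target_their_estimands(self):
        """At moderate n the matched analysis tracks the constant HR
        and the unmatched analysis tracks the pooled estimand."""
        sc = table2_preset(5)  # HR 2.5 constant, strong migration
        df = convergence_report(sc, ["risk_set", "unmatched_density"], 50_000, 6, seed=23)
        df = df.set_index("design")
        assert df.loc["risk_set", "target"] == pytest.approx(2.5, abs=1e-9)
        assert abs(df.loc["risk_set", "z"]) < 3
        assert df.loc["unmatched_density", "target"] == pytest.approx(2.31, abs=0.01)
        assert abs(df.loc["unmatched_density", "z"]) < 3

    def test_fixed_exposure_designs_hit_classical_targets(self):
        """Cumulative sampling recovers ad/bc and case-cohort sampling
        the risk ratio on a no-migration scenario."""
        sc = table2_preset(4)
        df = convergence_report(sc, ["cumulative", "case_cohort"], 50_000, 6, seed=29)
        df = df.set_index("design")
        assert df.loc["cumulative", "target_name"] == "population_or"
        assert df.loc["case_cohort", "target_name"] == "risk_ratio"
        assert abs(df.loc["cumulative", "z"]) < 3
        assert abs(df.loc["case_cohort", "z"]) < 3
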