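import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from spirosim import (
    NonRepeatablePolicy,
    ProtocolConfig,
    SimulationConfig,
    StopRule,
    SubjectProfile,
    apply_ats_protocol,
    cdf_comparison,
    derive_sigmas,
    measurement_error_summary,
    pair_failure_probability,
    rejection_curve,
    sensitivity_grid,
    simulate_cohort,
)
from spirosim.analysis import first_qualifying_vector, prefix_top_two_gaps
from spirosim.reference import RoundingMode

FIXED3 = ProtocolConfig(stop_rule=StopRule.fixed(3))


def top_two_gap_exceedance(m: int, rc: float, sigma: float) -> float:
    """Numeric-integration oracle: P(max - 2nd max of m iid N(0, sigma^2) > rc).

    Conditioning on which draw is the maximum (m ways) at value x, the
    other m-1 must all lie below x - rc.
    """
    z = rc / sigma
    integrand = lambda x: m * norm.pdf(x) * norm.cdf(x - z) ** (m - 1)
    value, _ = quad(integrand, -np.inf, np.inf)
    return value


class TestPairFailureProbability:
    def test_quoted_values(self):
        assert pair_failure_probability(0.15, 0.21) == pytest.approx(0.613, abs=1e-3)
        assert pair_failure_probability(0.15, 0.1065) == pytest.approx(0.319, abs=1e-3)

    def test_zero_sigma(self):
        assert pair_failure_probability(0.15, 0.0) == 0.0

    def test_closed_form_oracle(self):
        # independent route: P(|X1-X2| > rc) by 1-d integration over X1
        rc, sigma = 0.12, 0.3
        integrand = lambda x: norm.pdf(x) * (norm.cdf(x - rc / sigma) + norm.sf(x + rc / sigma))
        expected, _ = quad(integrand, -np.inf, np.inf)
        assert pair_failure_probability(rc, sigma) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("rc,sigma", [(0.05, 0.1), (0.15, 0.21), (0.3, 0.05)])
    def test_monte_carlo_agreement(self, rc, sigma, rng):
        n = 40_000
        draws = rng.normal(0.0, sigma, size=(n, 2))
        p_hat = np.mean(np.abs(draws[:, 0] - draws[:, 1]) > rc)
        p = pair_failure_probability(rc, sigma)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se

    def test_validation(self):
        with pytest.raises(ValueError):
            pair_failure_probability(0.0, 0.2)
        with pytest.raises(ValueError):
            pair_failure_probability(0.15, -0.1)


class TestPrefixMachinery:
    def test_gaps_match_scalar_sort(self, rng):
        man = rng.normal(3.5, 0.2, size=(50, 8))
        gaps = prefix_top_two_gaps(man)
        for m in range(3, 9):
            for i in range(50):
                top = sorted(man[i, :m], reverse=True)
                assert gaps[m][i] == pytest.approx(top[0] - top[1])

    def test_first_qualifying_matches_scalar_protocol(self, rng):
        man = rng.normal(3.5, 0.25, size=(400, 8))
        fq = first_qualifying_vector(man, 0.15)
        config = ProtocolConfig(stop_rule=StopRule.early())
        for i in range(400):
            out = apply_ats_protocol(man[i], config)
            assert (out.stop_maneuver or 0) == fq[i]


class TestMeasurementErrorSummary:
    def test_zero_intratest_sd_zero_error(self, default_subject):
        v = derive_sigmas(default_subject, 0.03, 0.0, RoundingMode.EXACT)
        cohort = simulate_cohort(SimulationConfig(default_subject, v, n_tests=2000, seed=5))
        summary = measurement_error_summary(cohort, FIXED3)
        assert summary.mean_error == 0.0
        assert summary.n_retained == 2000
        assert all(q == 0.0 for q in summary.error_quantiles.values())

    def test_within_test_matches_brute_force(self, default_subject, default_variability):
        cohort = simulate_cohort(
            SimulationConfig(default_subject, default_variability, n_tests=20, seed=11)
        )
        summary = measurement_error_summary(cohort, FIXED3, error_basis="within_test")
        errors = []
        for test in cohort:
            out = apply_ats_protocol(test.maneuvers, FIXED3)
            if out.reported_fev1 is not None:
                errors.append(out.unrestricted_max - out.reported_fev1)
        assert summary.n_retained == len(errors)
        assert summary.mean_error == pytest.approx(np.mean(errors))

    def test_population_matches_brute_force(self, default_subject, default_variability):
        cohort = simulate_cohort(
            SimulationConfig(default_subject, default_variability, n_tests=30, seed=12)
        )
        summary = measurement_error_summary(cohort, FIXED3)
        reported, unrestricted = [], []
        for test in cohort:
            out = apply_ats_protocol(test.maneuvers, FIXED3)
            unrestricted.append(out.unrestricted_max)
            if out.reported_fev1 is not None:
                reported.append(out.reported_fev1)
        assert summary.mean_error == pytest.approx(np.mean(unrestricted) - np.mean(reported))

    def test_errors_nonnegative(self, small_cohort):
        for basis in ("population", "within_test"):
            summary = measurement_error_summary(small_cohort, FIXED3, error_basis=basis)
            assert summary.mean_error >= 0.0
        within = measurement_error_summary(small_cohort, FIXED3, error_basis="within_test")
        quantiles = list(within.error_quantiles.values())
        assert all(q >= 0 for q in quantiles)
        assert quantiles == sorted(quantiles)

    def test_report_highest_keeps_all_tests(self, small_cohort):
        config = ProtocolConfig(
            stop_rule=StopRule.fixed(3), nonrepeatable_policy=NonRepeatablePolicy.REPORT_HIGHEST
        )
        summary = measurement_error_summary(small_cohort, config)
        assert summary.n_retained == len(small_cohort)

    def test_denominator_rules(self, small_cohort, default_subject):
        kwargs = dict(predicted_fev1=default_subject.predicted_fev1)
        reported = measurement_error_summary(small_cohort, FIXED3, "reported", **kwargs)
        predicted = measurement_error_summary(small_cohort, FIXED3, "predicted", **kwargs)
        unrestricted = measurement_error_summary(small_cohort, FIXED3, "unrestricted", **kwargs)
        assert reported.mean_error_pct > unrestricted.mean_error_pct > 0
        assert predicted.mean_error_pct > 0
        with pytest.raises(ValueError):
            measurement_error_summary(small_cohort, FIXED3, "baseline")

    def test_all_rejected_is_explicit_error(self, default_subject):
        v = derive_sigmas(default_subject, 0.0, 0.06)
        cohort = simulate_cohort(SimulationConfig(default_subject, v, n_tests=50, seed=3))
        tight = ProtocolConfig(rc=1e-9, stop_rule=StopRule.fixed(3))
        with pytest.raises(ValueError, match="all tests rejected"):
            measurement_error_summary(cohort, tight)


class TestRejectionCurve:
    def test_zero_cv_is_identically_zero(self):
        curve = rejection_curve(0.0, n_tests=100, seed=1)
        assert set(curve.points) == set(range(3, 9))
        assert all(v == 0.0 for v in curve.points.values())

    def test_nonincreasing_and_bounded(self):
        curve = rejection_curve(0.06, n_tests=5000, seed=2)
        values = [curve.points[m] for m in sorted(curve.points)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_m3_matches_integration_oracle(self):
        # first-three rejection at sigma_m = 0.21, rc = 0.15
        curve = rejection_curve(0.06, n_tests=20_902, seed=3)
        p = top_two_gap_exceedance(3, 0.15, 0.21)
        se = math.sqrt(p * (1 - p) / 20_902)
        assert abs(curve.points[3] - p) < 3 * se

    def test_two_maneuver_simulation_vs_analytic_grid(self, default_subject, rng):
        for rc, cv in ((0.10, 0.04), (0.15, 0.06), (0.20, 0.08)):
            v = derive_sigmas(default_subject, 0.03, cv, RoundingMode.EXACT)
            cohort = simulate_cohort(
                SimulationConfig(default_subject, v, n_tests=20_000, n_maneuvers=2,
                                 seed=int(rng.integers(2**31)))
            )
            gap = np.abs(cohort.maneuvers[:, 0] - cohort.maneuvers[:, 1])
            p = pair_failure_probability(rc, v.sigma_m)
            se = math.sqrt(p * (1 - p) / 20_000)
            assert abs(np.mean(gap > rc) - p) < 3 * se


class TestSensitivityGrid:
    @pytest.fixture(scope="class")
    def grid(self):
        return sensitivity_grid(
            [0.10, 0.15, 0.20], [0.0, 0.03, 0.06, 0.09, 0.12], n_tests=6000, seed=42
        )

    def test_shape(self, grid):
        assert len(grid) == 15

    def test_zero_cv_column_all_zero(self, grid):
        for cell in grid:
            if cell.cv_m == 0.0:
                assert cell.mean_error == 0.0
                assert cell.mean_error_pct == 0.0

    def test_error_strictly_increasing_in_cv_m(self, grid):
        for rc in (0.10, 0.15, 0.20):
            row = [c.mean_error for c in sorted(
                (c for c in grid if c.rc == rc), key=lambda c: c.cv_m)]
            assert all(a < b for a, b in zip(row, row[1:]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_grid([], [0.06], n_tests=10, seed=0)


class TestCdfComparison:
    def test_zero_sigma_identical_distributions(self, default_subject):
        v = derive_sigmas(default_subject, 0.03, 0.0, RoundingMode.EXACT)
        cohort = simulate_cohort(SimulationConfig(default_subject, v, n_tests=500, seed=6))
        comparison = cdf_comparison(cohort, FIXED3)
        assert comparison.protocol_quantiles == comparison.unrestricted_quantiles
        assert all(d == 0.0 for d in comparison.error_at_quantile)

    def test_unrestricted_dominates(self, small_cohort):
        comparison = cdf_comparison(small_cohort, FIXED3)
        assert all(u >= p for u, p in
                   zip(comparison.unrestricted_quantiles, comparison.protocol_quantiles))

    def test_median_gap_consistent_with_mean_error(self, default_cohort):
        comparison = cdf_comparison(default_cohort, FIXED3, unrestricted_over="all")
        summary = measurement_error_summary(default_cohort, FIXED3)
        median_gap = comparison.error_at_quantile[comparison.probs.index(0.5)]
        spread = max(comparison.error_at_quantile) - min(comparison.error_at_quantile)
        assert abs(median_gap - summary.mean_error) <= spread

    def test_invalid_choice(self, small_cohort):
        with pytest.raises(ValueError):
            cdf_comparison(small_cohort, FIXED3, unrestricted_over="some")
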