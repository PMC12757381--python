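"""Least-squares and maximum-likelihood estimation against exact oracles."""

import itertools
import math

import numpy as np
import pytest

from acsidm import (
    ACSTable,
    THETA_TRUE,
    OptimizerConfig,
    ParameterVector,
    SolveSpec,
    fit_least_squares,
    fit_maximum_likelihood,
    ls_objective,
    ml_loglik,
    multinomial_loglik,
    relative_errors,
    run_recovery_experiment,
)
from acsidm.estimation import _model_fractions, default_initial_parameters

#: rates low enough to underflow to exactly zero, freezing p at (1,0,0,0)
FROZEN = ParameterVector(30.0, 0.0, -800.0, 0.1, -800.0, 0.1)


def brute_force_multinomial_log_pmf(counts, probs):
    """Enumerate all outcome sequences; sum the probabilities of those
    matching the count vector."""
    n = int(sum(counts))
    total = 0.0
    for outcome in itertools.product(range(len(probs)), repeat=n):
        tally = [outcome.count(j) for j in range(len(probs))]
        if tally == list(counts):
            total += math.prod(probs[j] for j in outcome)
    return math.log(total)


class TestLeastSquaresObjective:
    def test_perfect_fit_has_zero_residual(self):
        # frozen dynamics give p = (1,0,0,0) exactly at every age
        acs = ACSTable(
            times=np.array([0.0, 50.0, 100.0]),
            counts=np.array([[7, 0, 0, 0]] * 3),
        )
        assert ls_objective(FROZEN, acs) == 0.0

    def test_hand_computed_single_cross_section(self):
        # p_model = (1,0,0,0); observed fractions (0.75, 0.15, 0.05, 0.05)
        acs = ACSTable(times=np.array([50.0]), counts=np.array([[75, 15, 5, 5]]))
        expected = 0.25**2 + 0.15**2 + 0.05**2 + 0.05**2
        assert ls_objective(FROZEN, acs) == pytest.approx(expected, abs=1e-15)

    def test_truth_beats_perturbed_onset_on_reference_data(self, reference_table):
        shifted = ParameterVector(50.0, 1 / 2000, -10.7, 0.1, -10.0, 0.1)
        at_truth = ls_objective(THETA_TRUE, reference_table)
        assert 0.0 < at_truth < ls_objective(shifted, reference_table)

    def test_objective_decomposes_over_cross_sections(self, reference_table):
        # equal weighting: the full objective is the sum of per-row
        # objectives, hence invariant to row order
        whole = ls_objective(THETA_TRUE, reference_table)
        parts = sum(
            ls_objective(
                THETA_TRUE,
                ACSTable(
                    times=reference_table.times[[k]],
                    counts=reference_table.counts[[k]],
                ),
            )
            for k in range(reference_table.times.size)
        )
        assert whole == pytest.approx(parts, rel=1e-12)


class TestMultinomialLoglik:
    def test_degenerate_distribution_scores_zero(self):
        assert multinomial_loglik([3, 0, 0, 0], [1.0, 0.0, 0.0, 0.0]) == 0.0

    def test_matches_brute_force_enumeration(self):
        counts = (2, 1, 0, 0)
        probs = (0.5, 0.25, 0.125, 0.125)
        oracle = brute_force_multinomial_log_pmf(counts, probs)
        assert multinomial_loglik(counts, probs) == pytest.approx(oracle, abs=1e-12)
        # the matched pmf value is 3 * 0.5^2 * 0.25
        assert math.exp(oracle) == pytest.approx(0.1875, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            multinomial_loglik([-1, 2, 0, 0], [0.25] * 4)

    def test_truth_usually_beats_distorted_mortality(self, theta_true):
        # 30% inflation of the Gompertz slope is the largest distortion
        # the 0.1-year RK4 grid still integrates stably (the hazard at
        # age 100 grows like exp(100 * theta4))
        distorted = ParameterVector(30.0, 1 / 2000, -10.7, 0.13, -10.0, 0.1)
        wins = 0
        for seed in range(20):
            report = run_recovery_experiment(
                theta_true, 2000, np.arange(0.0, 101.0, 10.0), seed, methods=()
            )
            if ml_loglik(theta_true, report.acs) > ml_loglik(distorted, report.acs):
                wins += 1
        assert wins > 10

    def test_runaway_mortality_slope_raises_instability(self, theta_true, reference_table):
        from acsidm.ode import NumericalInstabilityError

        doubled = ParameterVector(30.0, 1 / 2000, -10.7, 0.2, -10.0, 0.1)
        with pytest.raises(NumericalInstabilityError):
            ml_loglik(doubled, reference_table)


class TestRelativeErrors:
    def test_exact_estimate_has_zero_error(self, theta_true):
        assert np.all(relative_errors(theta_true, theta_true) == 0.0)

    def test_published_error_convention(self, theta_true):
        # onset estimated at 30.3 vs 30 is a 1.0% error; a slope of
        # 5.35 vs 5 per 10,000 is 7.0%
        hat = ParameterVector(30.3, 5.35e-4, -10.7, 0.1, -10.0, 0.1)
        errors = relative_errors(hat, theta_true)
        assert errors[0] == pytest.approx(0.010, abs=1e-12)
        assert errors[1] == pytest.approx(0.07, abs=1e-12)

    def test_zero_reference_rejected(self, theta_true):
        zero_ref = ParameterVector(0.0, 1 / 2000, -10.7, 0.1, -10.0, 0.1)
        with pytest.raises(ValueError):
            relative_errors(theta_true, zero_ref)


class TestFitting:
    def test_noise_free_identifiability_both_methods(self, monitoring_times):
        # expected counts computed exactly from the ODE at theta0; both
        # estimators must recover theta0 from a +/-10% perturbed start
        theta0 = ParameterVector(28.0, 4e-4, -10.2, 0.095, -9.6, 0.105)
        spec = SolveSpec()
        expected = 1000.0 * _model_fractions(
            theta0.as_array(), monitoring_times, spec
        )
        acs = ACSTable(
            times=monitoring_times,
            counts=np.zeros((monitoring_times.size, 4), dtype=int),
        )
        rng = np.random.default_rng(42)
        init = ParameterVector.from_array(
            theta0.as_array() * rng.uniform(0.9, 1.1, 6)
        )
        config = OptimizerConfig(n_restarts=2)
        for fitter in (fit_least_squares, fit_maximum_likelihood):
            result = fitter(acs, init, config=config, spec=spec, counts=expected)
            assert result.converged
            assert np.max(relative_errors(result.theta_hat, theta0)) < 1e-3

    def test_ml_optimum_dominates_truth(self, theta_true, monitoring_times):
        report = run_recovery_experiment(
            theta_true, 10000, monitoring_times, 4, methods=("maximum_likelihood",),
            init="perturbed-truth",
        )
        fitted = report.results["maximum_likelihood"]
        assert fitted.objective >= ml_loglik(theta_true, report.acs) - 1e-6

    def test_start_at_noiseless_optimum_stays_there(self, monitoring_times):
        theta0 = ParameterVector(30.0, 5e-4, -10.7, 0.1, -10.0, 0.1)
        spec = SolveSpec()
        expected = 5000.0 * _model_fractions(
            theta0.as_array(), monitoring_times, spec
        )
        acs = ACSTable(
            times=monitoring_times,
            counts=np.zeros((monitoring_times.size, 4), dtype=int),
        )
        result = fit_maximum_likelihood(
            acs, theta0, config=OptimizerConfig(n_restarts=0), spec=spec,
            counts=expected,
        )
        assert np.max(relative_errors(result.theta_hat, theta0)) < 1e-4


class TestRecoveryExperiment:
    def test_empty_population_rejected(self, theta_true, monitoring_times):
        with pytest.raises(ValueError):
            run_recovery_experiment(theta_true, 0, monitoring_times, 1)

    def test_same_seed_reproduces_report(self, theta_true, monitoring_times):
        config = OptimizerConfig(max_iter=120, n_restarts=0)
        kwargs = dict(
            methods=("maximum_likelihood",), init="perturbed-truth", config=config
        )
        a = run_recovery_experiment(theta_true, 2000, monitoring_times, 5, **kwargs)
        b = run_recovery_experiment(theta_true, 2000, monitoring_times, 5, **kwargs)
        assert np.array_equal(a.acs.counts, b.acs.counts)
        assert (
            a.results["maximum_likelihood"].theta_hat
            == b.results["maximum_likelihood"].theta_hat
        )

    def test_default_init_is_data_driven(self, reference_table):
        init = default_initial_parameters(reference_table)
        # first diseased counts appear at age 40; one interval earlier is 30
        assert init.theta1 == 30.0
        assert init.theta2 > 0
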