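import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from pirogue.hmm_core import (
    KAPPA_MAX,
    FitOptions,
    HmmParameters,
    StateEmission,
    StateSequence,
    fit,
    forward_loglik,
    gamma_logpdf,
    initial_params_from_labels,
    pseudo_residuals,
    stationary_distribution,
    viterbi_decode,
    vonmises_logpdf,
)
from pirogue.preprocess import StepSeries, steps_and_angles
from pirogue.synthetic_data import simulate_trip

T0 = np.datetime64("2014-03-01T06:00:00")


def make_series(step, angle=None, trip_id="s"):
    step = np.asarray(step, dtype=float)
    if angle is None:
        angle = np.zeros(max(len(step) - 1, 0))
    return StepSeries(trip_id, 5.0, T0, step, np.asarray(angle, dtype=float))


def random_params(rng, n=2):
    ems = [
        StateEmission(
            step_mean=float(rng.uniform(5, 50)),
            step_sd=float(rng.uniform(2, 20)),
            angle_mean=float(rng.uniform(-3, 3)),
            angle_concentration=float(rng.uniform(0.05, 5)),
        )
        for _ in range(n)
    ]
    names = ("fishing", "non_fishing") if n == 2 else tuple(f"s{i}" for i in range(n))
    return HmmParameters(
        pi=rng.dirichlet(np.full(n, 2.0)),
        A=rng.dirichlet(np.full(n, 2.0), size=n),
        emissions=ems,
        state_names=names,
    )


def brute_force(params, series):
    """Exhaustive path enumeration oracle for forward and Viterbi."""
    step = series.step.copy()
    step[step <= 0] = np.nan
    angle = np.full_like(step, np.nan)
    if len(series.angle):
        angle[1:] = series.angle
    T, N = len(step), params.n_states

    def logb(t, j):
        e = params.emissions[j]
        v = 0.0
        if not np.isnan(step[t]):
            v += gamma_logpdf(step[t], e.step_mean, e.step_sd)
        if not np.isnan(angle[t]):
            v += vonmises_logpdf(angle[t], e.angle_mean, e.angle_concentration)
        return v

    total = -np.inf
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(N), repeat=T):
        lp = math.log(params.pi[path[0]]) + logb(0, path[0])
        for t in range(1, T):
            lp += math.log(params.A[path[t - 1], path[t]]) + logb(t, path[t])
        total = np.logaddexp(total, lp)
        if lp > best_lp:  # ties to the lexicographically first = lower index
            best_lp, best_path = lp, path
    return total, best_lp, best_path


class TestGammaLogpdf:
    def test_exponential_reduction(self):
        # shape 1: log f(x) = log(rate) - rate*x; at x = mean, rate = 1/mean
        mean = 37.0
        assert gamma_logpdf(mean, mean, mean) == pytest.approx(math.log(1 / mean) - 1.0)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda x: math.exp(gamma_logpdf(x, 300.0, 150.0)), 0, 200 * 300.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_grid_argmax(self):
        mean, sd = 20.0, 8.0
        shape, rate = (mean / sd) ** 2, mean / sd**2
        grid = np.linspace(0.01, 100, 200001)
        argmax = grid[np.argmax(gamma_logpdf(grid, mean, sd))]
        assert argmax == pytest.approx((shape - 1) / rate, abs=1e-3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            gamma_logpdf(1.0, -1.0, 1.0)


class TestVonMisesLogpdf:
    def test_uniform_limit(self):
        for th in (-3.0, 0.0, 1.5, np.pi):
            assert vonmises_logpdf(th, 0.3, 0.0) == pytest.approx(-math.log(2 * math.pi))

    def test_symmetry_about_mean(self):
        mu = 0.7
        for d in (0.1, 1.0, 2.0):
            assert vonmises_logpdf(mu + d, mu, 2.5) == pytest.approx(
                vonmises_logpdf(mu - d, mu, 2.5)
            )

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda t: math.exp(vonmises_logpdf(t, 0.4, 2.0)), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_large_kappa_finite(self):
        assert np.isfinite(vonmises_logpdf(0.0, 0.0, KAPPA_MAX))


class TestForward:
    def test_single_observation_closed_form(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        ss = make_series([12.0], angle=[])
        expected = np.logaddexp(
            math.log(p.pi[0]) + gamma_logpdf(12.0, p.emissions[0].step_mean, p.emissions[0].step_sd),
            math.log(p.pi[1]) + gamma_logpdf(12.0, p.emissions[1].step_mean, p.emissions[1].step_sd),
        )
        assert forward_loglik(p, ss) == pytest.approx(expected, rel=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = random_params(rng)
            ss = make_series(rng.gamma(4, 8, 8), rng.vonmises(0, 1, 7))
            total, _, _ = brute_force(p, ss)
            assert forward_loglik(p, ss) == pytest.approx(total, rel=1e-10)

    def test_three_states_enumeration(self):
        rng = np.random.default_rng(3)
        p = random_params(rng, n=3)
        ss = make_series(rng.gamma(4, 8, 6), rng.vonmises(0, 1, 5))
        total, _, _ = brute_force(p, ss)
        assert forward_loglik(p, ss) == pytest.approx(total, rel=1e-10)

    def test_all_missing_gives_zero(self):
        rng = np.random.default_rng(4)
        p = random_params(rng)
        ss = make_series([0.0, 0.0, 0.0], [np.nan, np.nan])
        assert forward_loglik(p, ss) == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_params_rejected(self):
        p = random_params(np.random.default_rng(5))
        p.pi = np.array([np.nan, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            forward_loglik(p, make_series([1.0, 2.0]))


class TestViterbi:
    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            p = random_params(rng)
            ss = make_series(rng.gamma(4, 8, 8), rng.vonmises(0, 1, 7))
            _, best_lp, best_path = brute_force(p, ss)
            dec = viterbi_decode(p, ss)
            assert tuple(dec.labels) == best_path
            assert dec.log_joint == pytest.approx(best_lp, rel=1e-10)

    def test_absorbing_chain_ignores_observations(self):
        rng = np.random.default_rng(7)
        p = random_params(rng)
        p.A = np.eye(2)
        p.pi = np.array([1.0, 0.0])
        ss = make_series(rng.gamma(4, 8, 20), rng.vonmises(0, 1, 19))
        dec = viterbi_decode(p, ss)
        assert np.all(dec.labels == 0)

    def test_log_joint_never_exceeds_forward(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = random_params(rng)
            ss = make_series(rng.gamma(4, 8, 12), rng.vonmises(0, 1, 11))
            assert viterbi_decode(p, ss).log_joint <= forward_loglik(p, ss) + 1e-12

    def test_decode_accuracy_on_separated_states(self, separated_profile):
        sim = simulate_trip(separated_profile, seed=11, duration_h=10000 * 5 / 3600.0)
        ss = steps_and_angles(sim.trip)
        p = HmmParameters(
            pi=np.array([0.5, 0.5]),
            A=separated_profile.A,
            emissions=list(separated_profile.emissions),
        )
        dec = viterbi_decode(p, ss)
        assert np.mean(dec.labels == sim.truth.labels) >= 0.95


class TestPermutationInvariance:
    def test_likelihood_invariant_labels_permute(self):
        rng = np.random.default_rng(9)
        p = random_params(rng)
        q = p.permuted([1, 0])
        ss = make_series(rng.gamma(4, 8, 15), rng.vonmises(0, 1, 14))
        assert forward_loglik(p, ss) == pytest.approx(forward_loglik(q, ss), rel=1e-12)
        dp, dq = viterbi_decode(p, ss), viterbi_decode(q, ss)
        np.testing.assert_array_equal(dp.labels, 1 - dq.labels)


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        d = stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        np.testing.assert_allclose(d, [0.5, 0.5], atol=1e-12)

    def test_identity_is_reducible(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(2))

    def test_fixed_point(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            A = rng.dirichlet((2, 2), size=2)
            d = stationary_distribution(A)
            np.testing.assert_allclose(d @ A, d, atol=1e-12)
            assert d.sum() == pytest.approx(1.0, abs=1e-12)


class TestInitialParamsFromLabels:
    def test_single_state_labels_error(self):
        ss = make_series([1.0, 2.0, 3.0], [0.1, 0.2])
        lab = StateSequence("s", np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="non_fishing"):
            initial_params_from_labels([ss], [lab])

    def test_recovers_generator_moments(self, separated_profile):
        sims = [
            simulate_trip(separated_profile, seed=900 + i, duration_h=2500 * 5 / 3600.0)
            for i in range(4)
        ]
        series = [steps_and_angles(s.trip) for s in sims]
        labels = [s.truth for s in sims]
        p = initial_params_from_labels(series, labels)
        for j, e_true in enumerate(separated_profile.emissions):
            n_j = sum(int(np.sum(s.truth.labels == j)) for s in sims)
            se = e_true.step_sd / math.sqrt(n_j)
            assert abs(p.emissions[j].step_mean - e_true.step_mean) < 3 * se

    def test_degenerate_angles_cap_kappa(self):
        ss = make_series(np.full(6, 10.0), np.full(5, 0.3))
        lab = StateSequence("s", np.array([0, 0, 0, 1, 1, 1]))
        p = initial_params_from_labels([ss], [lab])
        assert p.emissions[0].angle_concentration == KAPPA_MAX

    def test_misaligned_labels_error(self):
        ss = make_series([1.0, 2.0, 3.0], [0.1, 0.2])
        lab = StateSequence("s", np.array([0, 1]))
        with pytest.raises(ValueError, match="labels"):
            initial_params_from_labels([ss], [lab])


class TestFit:
    def test_loglik_at_least_truth(self, separated_profile):
        sim = simulate_trip(separated_profile, seed=21, duration_h=800 * 5 / 3600.0)
        ss = steps_and_angles(sim.trip)
        truth_params = HmmParameters(
            pi=np.array([0.5, 0.5]),
            A=separated_profile.A,
            emissions=list(separated_profile.emissions),
        )
        res = fit([ss], truth_params, FitOptions(n_restarts=1, maxiter=100))
        assert res.loglik >= forward_loglik(truth_params, ss) - 1e-8

    def test_monotone_vs_init(self, separated_profile, small_sim):
        ss = steps_and_angles(small_sim.trip)
        init = initial_params_from_labels([ss], [small_sim.truth])
        res = fit([ss], init, FitOptions(n_restarts=1, maxiter=50))
        assert res.loglik >= forward_loglik(init, ss) - 1e-8

    def test_fishing_state_has_smaller_step_mean(self, small_sim):
        ss = steps_and_angles(small_sim.trip)
        init = initial_params_from_labels([ss], [small_sim.truth])
        res = fit([ss], init.permuted([1, 0]), FitOptions(n_restarts=1, maxiter=50))
        assert res.params.state_names[0] == "fishing"
        assert res.params.emissions[0].step_mean < res.params.emissions[1].step_mean

    def test_identical_states_warn_flat_likelihood(self):
        rng = np.random.default_rng(30)
        steps = rng.gamma(4.0, 5.0, 400)
        ss = make_series(steps, rng.vonmises(0, 0.5, 399))
        e = StateEmission(20.0, 10.0, 0.0, 0.5)
        init = HmmParameters(
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emissions=[e, StateEmission(20.0, 10.0, 0.0, 0.5)],
        )
        res = fit([ss], init, FitOptions(n_restarts=1, maxiter=30))
        assert res.converged
        # single-state data: either flagged flat or states collapsed
        means = [em.step_mean for em in res.params.emissions]
        assert res.warnings or abs(means[0] - means[1]) / max(means) < 0.5


class TestPseudoResiduals:
    def test_first_observation_uses_pi(self):
        p = HmmParameters(
            pi=np.array([0.3, 0.7]),
            A=np.array([[0.8, 0.2], [0.2, 0.8]]),
            emissions=[StateEmission(10.0, 5.0), StateEmission(20.0, 8.0)],
        )
        ss = make_series([15.0, 20.0], [np.nan])
        r = pseudo_residuals(p, ss)
        u = sum(
            p.pi[j]
            * stats.gamma.cdf(
                15.0, p.emissions[j].gamma_shape, scale=1 / p.emissions[j].gamma_rate
            )
            for j in range(2)
        )
        assert r.step[0] == pytest.approx(stats.norm.ppf(u), rel=1e-9)

    def test_tail_observation_large_residual(self):
        p = HmmParameters(
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emissions=[StateEmission(5.0, 2.0), StateEmission(10.0, 3.0)],
        )
        ss = make_series([200.0, 200.0, 200.0], [0.0, 0.0])
        r = pseudo_residuals(p, ss)
        assert np.all(np.abs(r.step) > 3.0)

    def test_calibration_under_correct_model(self, separated_profile):
        # under the generating model, stream residuals are iid N(0, 1)
        passes = 0
        n_rep = 60
        p = HmmParameters(
            pi=np.array([0.5, 0.5]),
            A=separated_profile.A,
            emissions=list(separated_profile.emissions),
        )
        for i in range(n_rep):
            sim = simulate_trip(separated_profile, seed=5000 + i, duration_h=300 * 5 / 3600.0)
            ss = steps_and_angles(sim.trip)
            r = pseudo_residuals(p, ss)
            z = np.concatenate([r.step[~np.isnan(r.step)], r.angle[~np.isnan(r.angle)]])
            if stats.kstest(z, "norm").pvalue > 0.01:
                passes += 1
        assert passes >= math.floor(0.95 * n_rep)

    def test_missing_observations_give_missing_residuals(self):
        p = random_params(np.random.default_rng(33))
        ss = make_series([10.0, 0.0, 12.0], [np.nan, 0.2])
        r = pseudo_residuals(p, ss)
        assert np.isnan(r.step[1])
        assert np.isnan(r.angle[0])  # first observation never has an angle
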