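import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinecarve.errors import DegenerateClassError, DegenerateInputError
from spinecarve.hmc import (
    HMCParams,
    convergence_rate,
    forward_backward,
    ml_estimate,
    mpm_classify,
    sample_posterior_chain,
    sem_estimate,
    simulate_hmc_chain,
)

from tests.helpers import (
    enumerate_posterior,
    enumerate_sequence_posterior,
    random_params,
)

WELL_SEPARATED = HMCParams(
    (0.5, 0.5), ((0.95, 0.05), (0.05, 0.95)), (0.25, 0.75), (0.05, 0.05)
)


class TestForwardBackward:
    def test_single_node_posterior(self):
        p = HMCParams((0.3, 0.7), ((0.5, 0.5), (0.5, 0.5)), (0.0, 1.0), (1.0, 1.0))
        y = np.array([0.2])
        _, _, xi = forward_backward(p, y)
        from tests.helpers import gauss_pdf

        w0 = 0.3 * gauss_pdf(0.2, 0.0, 1.0)
        w1 = 0.7 * gauss_pdf(0.2, 1.0, 1.0)
        np.testing.assert_allclose(xi[0], [w0 / (w0 + w1), w1 / (w0 + w1)],
                                   atol=1e-12)

    def test_uninformative_emissions_return_prior_marginals(self):
        # identical emissions for both classes: posterior = chain prior
        p = HMCParams((0.9, 0.1), ((0.7, 0.3), (0.4, 0.6)), (0.5, 0.5), (1.0, 1.0))
        y = np.random.default_rng(0).normal(0.5, 1.0, size=6)
        _, _, xi = forward_backward(p, y)
        pi = np.array(p.pi)
        Pi = np.array(p.Pi)
        marg = pi.copy()
        for n in range(6):
            np.testing.assert_allclose(xi[n], marg, atol=1e-12)
            marg = marg @ Pi

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            N = int(rng.integers(2, 9))
            p = random_params(rng)
            _, y = simulate_hmc_chain(p, N, rng)
            _, _, xi = forward_backward(p, y)
            np.testing.assert_allclose(xi, enumerate_posterior(p, y), atol=1e-10)

    def test_rows_sum_to_one_on_long_chain(self):
        _, y = simulate_hmc_chain(WELL_SEPARATED, 30000, 0)
        alpha, beta, xi = forward_backward(WELL_SEPARATED, y)
        np.testing.assert_allclose(xi.sum(axis=1), 1.0, atol=1e-12)
        assert np.isfinite(alpha).all() and np.isfinite(beta).all()

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            HMCParams((0.5, 0.5), ((0.5, 0.5), (0.5, 0.5)), (0.0, 1.0), (0.0, 1.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(2, 10))
def test_forward_backward_oracle_property(seed, N):
    """Posterior marginals equal brute-force enumeration for any valid
    parameters and observations (chains short enough to enumerate)."""
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    _, y = simulate_hmc_chain(p, N, rng)
    _, _, xi = forward_backward(p, y)
    np.testing.assert_allclose(xi, enumerate_posterior(p, y), atol=1e-10)


class TestMpmClassify:
    def test_argmax_and_tie_rule(self):
        xi = np.array([[0.3, 0.7], [0.5, 0.5], [1.0, 0.0]])
        np.testing.assert_array_equal(mpm_classify(xi), [1, 0, 0])

    def test_mpm_minimizes_expected_per_site_error(self):
        # on an enumerable chain, MPM from xi beats every other labeling
        # in expected per-site error under p(x | y)
        rng = np.random.default_rng(5)
        p = random_params(rng)
        _, y = simulate_hmc_chain(p, 6, rng)
        _, _, xi = forward_backward(p, y)
        xhat = tuple(mpm_classify(xi))
        post = enumerate_sequence_posterior(p, y)

        def expected_errors(lab):
            return sum(
                pr * sum(a != b for a, b in zip(lab, xs))
                for xs, pr in post.items()
            )

        best = min(post.keys(), key=expected_errors)
        assert expected_errors(xhat) <= expected_errors(best) + 1e-12


class TestSamplePosteriorChain:
    def test_absorbing_dynamics_constant_chain(self):
        p = HMCParams((0.5, 0.5), ((1.0, 0.0), (0.0, 1.0)), (0.0, 1.0),
                      (0.01, 0.01))
        y = np.full(50, 1.0)  # peaked emission forces x_1 = 1
        x = sample_posterior_chain(p, y, rng=0)
        assert (x == 1).all()

    def test_sampling_distribution_equals_sequence_posterior(self):
        # exact check: the sampler's chain-rule factorization (initial
        # posterior x posterior transition probabilities) reproduces the
        # enumerated p(x | y) for every full sequence
        import itertools

        from spinecarve.hmc import _backward, _emission_densities

        rng = np.random.default_rng(11)
        p = HMCParams((0.6, 0.4), ((0.8, 0.2), (0.3, 0.7)), (0.0, 1.0),
                      (0.7, 0.7))
        _, y = simulate_hmc_chain(p, 6, rng)
        post = enumerate_sequence_posterior(p, y)
        pi, Pi, mu, sigma = p.arrays()
        f = _emission_densities(y, mu, sigma)
        beta = _backward(f, Pi)
        p1 = pi * f[0] * beta[0]
        p1 /= p1.sum()
        for xs in itertools.product((0, 1), repeat=6):
            pr = p1[xs[0]]
            for n in range(1, 6):
                q = Pi[xs[n - 1], :] * f[n, :] * beta[n, :]
                pr *= q[xs[n]] / q.sum()
            assert pr == pytest.approx(post[xs], abs=1e-12)

    def test_empirical_sequence_frequencies_match_enumeration(self):
        rng = np.random.default_rng(11)
        p = HMCParams((0.6, 0.4), ((0.8, 0.2), (0.3, 0.7)), (0.0, 1.0),
                      (0.7, 0.7))
        _, y = simulate_hmc_chain(p, 6, rng)
        post = enumerate_sequence_posterior(p, y)
        n_draws = 100_000
        counts: dict[tuple, int] = {}
        gen = np.random.default_rng(123)
        from spinecarve.hmc import _backward, _emission_densities

        pi, Pi, mu, sigma = p.arrays()
        f = _emission_densities(y, mu, sigma)
        beta = _backward(f, Pi)
        for _ in range(n_draws):
            x = tuple(sample_posterior_chain(p, y, beta=beta, rng=gen))
            counts[x] = counts.get(x, 0) + 1
        # 4 Monte-Carlo SEs: ~60 comparisons, keep the family-wise false
        # alarm probability negligible while still catching real bias
        for xs, pr in post.items():
            if pr < 1e-4:
                continue
            freq = counts.get(xs, 0) / n_draws
            se = np.sqrt(pr * (1 - pr) / n_draws)
            assert abs(freq - pr) <= 4 * se + 1e-9, (xs, freq, pr)

    def test_reproducible_given_seed(self):
        _, y = simulate_hmc_chain(WELL_SEPARATED, 200, 1)
        a = sample_posterior_chain(WELL_SEPARATED, y, rng=7)
        b = sample_posterior_chain(WELL_SEPARATED, y, rng=7)
        np.testing.assert_array_equal(a, b)


class TestMlEstimate:
    def test_alternating_sequence_deterministic_counts(self):
        x = np.array([0, 1] * 10)
        y = x.astype(float)
        p = ml_estimate(x, y)
        assert p.Pi[0][1] == 1.0 and p.Pi[1][0] == 1.0
        assert p.mu == (0.0, 1.0)
        assert p.sigma[0] == pytest.approx(1e-4)  # floored

    def test_single_class_raises_degenerate_signal(self):
        with pytest.raises(DegenerateClassError):
            ml_estimate(np.zeros(10, dtype=int), np.zeros(10))

    def test_matches_independent_counting_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, size=500)
        y = rng.normal(x, 0.3)
        p = ml_estimate(x, y)
        # plain-python counting oracle
        n0 = sum(1 for v in x if v == 0)
        n1 = len(x) - n0
        assert p.pi == pytest.approx((n0 / len(x), n1 / len(x)))
        for i in (0, 1):
            from_i = [(a, b) for a, b in zip(x[:-1], x[1:]) if a == i]
            for j in (0, 1):
                expect = sum(1 for _, b in from_i if b == j) / len(from_i)
                assert p.Pi[i][j] == pytest.approx(expect)
            vals = [v for c, v in zip(x, y) if c == i]
            assert p.mu[i] == pytest.approx(np.mean(vals))
            assert p.sigma[i] == pytest.approx(np.std(vals))


class TestConvergenceRate:
    def test_identical_zero_complementary_one(self):
        a = np.array([0, 1, 1, 0])
        assert convergence_rate(a, a) == 0.0
        assert convergence_rate(a, 1 - a) == 1.0

    def test_single_disagreement_fraction(self):
        a = np.zeros(100, dtype=int)
        b = a.copy()
        b[17] = 1
        assert convergence_rate(a, b) == pytest.approx(0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convergence_rate(np.zeros(3), np.zeros(4))


class TestSemEstimate:
    def test_parameter_recovery_on_simulated_chain(self):
        _, y = simulate_hmc_chain(WELL_SEPARATED, 50_000, 2)
        theta, trace = sem_estimate(y, rng_seed=3)
        assert abs(theta.mu[0] - 0.25) <= 0.01
        assert abs(theta.mu[1] - 0.75) <= 0.01
        assert abs(theta.sigma[0] - 0.05) <= 0.01
        assert abs(theta.sigma[1] - 0.05) <= 0.01
        assert abs(theta.Pi[0][0] - 0.95) <= 0.02
        assert abs(theta.Pi[1][1] - 0.95) <= 0.02

    def test_converges_quickly_under_own_model(self):
        # data drawn from the simple-init model itself stops within the
        # typical iteration budget
        _, y = simulate_hmc_chain(WELL_SEPARATED, 20_000, 5)
        _, trace = sem_estimate(y, rng_seed=6)
        assert len(trace) <= 15
        assert trace.epsilon[-1] is not None and trace.epsilon[-1] < 0.01

    def test_explicit_init_recorded_in_trace(self):
        ref = HMCParams((0.4, 0.6), ((0.9, 0.1), (0.2, 0.8)), (0.1, 0.9),
                        (0.2, 0.2))
        _, y = simulate_hmc_chain(WELL_SEPARATED, 2_000, 7)
        _, trace = sem_estimate(y, init=ref, rng_seed=8)
        assert trace.params[0] == ref

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            sem_estimate(np.full(100, 0.5), rng_seed=0)

    def test_deterministic_given_seed(self):
        _, y = simulate_hmc_chain(WELL_SEPARATED, 5_000, 9)
        t1, _ = sem_estimate(y, rng_seed=10)
        t2, _ = sem_estimate(y, rng_seed=10)
        assert t1 == t2


class TestSimulateHmcChain:
    def test_identity_transitions_freeze_state(self):
        p = HMCParams((0.5, 0.5), ((1.0, 0.0), (0.0, 1.0)), (0.0, 1.0),
                      (0.1, 0.1))
        x, _ = simulate_hmc_chain(p, 1000, 3)
        assert len(np.unique(x)) == 1

    def test_transition_frequencies_match_matrix(self):
        p = HMCParams((0.5, 0.5), ((0.9, 0.1), (0.3, 0.7)), (0.0, 1.0),
                      (0.5, 0.5))
        x, _ = simulate_hmc_chain(p, 1_000_000, 4)
        for i in (0, 1):
            sel = x[:-1] == i
            freq = np.mean(x[1:][sel] == 1)
            assert abs(freq - p.Pi[i][1]) <= 0.005

    def test_noiseless_limit_recovers_states(self):
        p = HMCParams((0.5, 0.5), ((0.8, 0.2), (0.2, 0.8)), (0.0, 1.0),
                      (1e-6, 1e-6))
        x, y = simulate_hmc_chain(p, 500, 5)
        np.testing.assert_array_equal((y > 0.5).astype(int), x)
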