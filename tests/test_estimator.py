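import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from bayesmi.baselines import plugin_entropy, plugin_information
from bayesmi.counts import CountsTable, counts_from_samples, multiplicities_from_counts
from bayesmi.estimator import (
    HyperParams,
    NoPeakError,
    alpha_map,
    beta_map,
    estimate,
    log_beta_prior,
    log_marginal_likelihood_alpha,
    log_marginal_likelihood_beta,
    posterior_mean_information,
    posterior_mean_information_dp,
    posterior_variance_information,
    prior_mean_information,
)

from conftest import mc_information_moments

SYM = np.array([0.5, 0.5])


class TestMarginalLikelihoodBeta:
    def test_single_state_one_one_beta2(self):
        # integral of q(1-q) against a uniform prior = 1/6
        c = counts_from_samples([("a", 0), ("a", 1)])
        assert np.exp(log_marginal_likelihood_beta(c, 2.0)) == pytest.approx(1 / 6, rel=1e-12)

    def test_singleton_table_is_flat_in_beta(self):
        c = counts_from_samples([(f"x{i}", i % 2) for i in range(8)])
        vals = log_marginal_likelihood_beta(c, np.array([0.1, 1.0, 10.0, 100.0]))
        assert np.ptp(vals) < 1e-9

    @pytest.mark.parametrize("beta", [0.1, 1.0, 10.0])
    def test_matches_quadrature_oracle(self, rng, beta):
        # brute-force numeric integration of the per-state Beta-binomial
        # integral, including an asymmetric empirical center
        counts = rng.integers(0, 4, size=(8, 2))
        counts[counts.sum(axis=1) == 0, 1] = 1
        c = CountsTable(tuple(f"x{i}" for i in range(8)), (0, 1), counts)
        q1 = c.q_y_hat[1]
        total = 0.0
        for n0, n1 in c.counts:
            val, _ = quad(
                lambda q: q ** n1 * (1 - q) ** n0 * beta_dist.pdf(q, beta * q1, beta * (1 - q1)),
                0, 1, epsabs=1e-13, epsrel=1e-13,
            )
            total += np.log(val)
        assert log_marginal_likelihood_beta(c, beta) == pytest.approx(total, abs=1e-8)

    def test_grouped_and_per_state_forms_agree(self, balanced_table):
        m = multiplicities_from_counts(balanced_table)
        grid = np.geomspace(1e-3, 1e3, 25)
        np.testing.assert_allclose(
            log_marginal_likelihood_beta(m, grid),
            log_marginal_likelihood_beta(balanced_table, grid),
            atol=1e-10,
        )

    def test_rejects_nonpositive_beta(self, balanced_table):
        with pytest.raises(ValueError):
            log_marginal_likelihood_beta(balanced_table, -1.0)


def _table_from_multiplicities(m11, m20, m10=0):
    """Build a binary table with the requested multiplicities and a
    symmetric Y marginal (padded with extra singletons if needed; singleton
    states never move f11 or the likelihood shape)."""
    pairs = []
    i = 0
    for _ in range(m11):
        pairs += [(f"p{i}", 0), (f"p{i}", 1)]
        i += 1
    for k in range(m20):
        y = k % 2
        pairs += [(f"d{i}", y), (f"d{i}", y)]
        i += 1
    for k in range(m10):
        pairs += [(f"s{i}", k % 2)]
        i += 1
    n1 = sum(1 for _, y in pairs if y == 1)
    n0 = len(pairs) - n1
    light = 1 if n1 < n0 else 0
    for _ in range(abs(n0 - n1)):
        pairs.append((f"b{i}", light))
        i += 1
    return counts_from_samples(pairs)


class TestBetaMap:
    def test_closed_form_example(self):
        # f11 = 1/4  ->  beta* = f11 / (1/2 - f11) = 1
        t = _table_from_multiplicities(m11=1, m20=3, m10=3)
        m = multiplicities_from_counts(t)
        assert m.symmetric
        assert m.f11 == 0.25
        assert beta_map(m) == pytest.approx(1.0)

    def test_infinite_when_f11_at_least_half(self):
        t = _table_from_multiplicities(m11=2, m20=2)
        m = multiplicities_from_counts(t)
        assert m.f11 == 0.5
        assert np.isinf(beta_map(m))

    def test_boundary_f11_zero(self):
        t = _table_from_multiplicities(m11=0, m20=4)
        m = multiplicities_from_counts(t)
        assert beta_map(m) <= 1e-4

    @pytest.mark.parametrize("m11,m20", [(1, 3), (2, 3), (3, 5), (1, 7)])
    def test_closed_form_matches_numeric_argmax(self, m11, m20):
        t = _table_from_multiplicities(m11, m20)
        m = multiplicities_from_counts(t)
        closed = beta_map(m)
        numeric = beta_map(m, center=SYM)  # force the grid/golden-section path
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_no_coincidences_raises(self):
        t = counts_from_samples([(f"x{i}", i % 2) for i in range(6)])
        with pytest.raises(NoPeakError):
            beta_map(multiplicities_from_counts(t))

    def test_singleton_states_do_not_move_beta_star(self):
        # p10(beta) is constant: appending balanced singletons (which keep
        # the center fixed) leaves the argmax untouched
        t1 = _table_from_multiplicities(m11=2, m20=5)
        t2 = _table_from_multiplicities(m11=2, m20=5, m10=6)
        b1 = beta_map(multiplicities_from_counts(t1), center=SYM)
        b2 = beta_map(multiplicities_from_counts(t2), center=SYM)
        assert b2 == pytest.approx(b1, rel=1e-6)


class TestPriorMeanInformation:
    def test_small_beta_limit_is_marginal_entropy(self):
        h = HyperParams(beta=1e-9, center=SYM)
        assert prior_mean_information(h) == pytest.approx(np.log(2), abs=1e-7)

    def test_large_beta_limit_is_zero(self):
        assert prior_mean_information(HyperParams(beta=1e9, center=SYM)) == pytest.approx(0.0, abs=1e-7)
        assert prior_mean_information(HyperParams(beta=np.inf, center=SYM)) == 0.0

    def test_beta2_closed_value(self):
        # log2 - psi(3) + psi(2) = log2 - 1/2
        h = HyperParams(beta=2.0, center=SYM)
        assert prior_mean_information(h) == pytest.approx(np.log(2) - 0.5, rel=1e-12)

    def test_strictly_decreasing_in_beta(self):
        grid = np.geomspace(1e-3, 1e3, 40)
        vals = [prior_mean_information(HyperParams(beta=b, center=SYM)) for b in grid]
        assert np.all(np.diff(vals) < 0)


class TestPosteriorMoments:
    def test_converges_to_plugin_with_dense_counts(self):
        base = np.array([[3, 1], [1, 3], [2, 2], [4, 0]])
        h_center = (base.sum(axis=0) / base.sum()).astype(float)
        diffs = []
        for scale in (1, 10, 100, 1000):
            c = CountsTable(tuple("abcd"), (0, 1), base * scale)
            h = HyperParams(beta=1.7, center=c.q_y_hat)
            diffs.append(abs(posterior_mean_information(c, h) - plugin_information(c)))
        assert all(np.diff(diffs) < 0)
        assert diffs[-1] < 1e-3

    def test_all_singletons_reduce_to_prior(self):
        c = counts_from_samples([(f"x{i}", i % 2) for i in range(20)])
        h = HyperParams(beta=1.7, center=SYM)
        assert posterior_mean_information(c, h) == pytest.approx(
            prior_mean_information(h), abs=1e-12
        )

    @pytest.mark.parametrize("beta", [0.7, 1.7])
    def test_mean_and_variance_match_mc_oracle(self, small_random_tables, beta):
        n_draws = 150_000
        for k, c in enumerate(small_random_tables[:5]):
            h = HyperParams(beta=beta, center=c.q_y_hat)
            mean, se_m, var, se_v = mc_information_moments(c, beta, c.q_y_hat, n_draws, seed=k)
            assert posterior_mean_information(c, h) == pytest.approx(mean, abs=3 * se_m)
            assert posterior_variance_information(c, h) == pytest.approx(var, abs=3 * se_v)

    def test_variance_halves_when_states_duplicated(self, balanced_table):
        c = balanced_table
        dup = CountsTable(
            tuple(f"{x}{s}" for s in "AB" for x in c.x_ids),
            c.y_ids,
            np.vstack([c.counts, c.counts]),
        )
        h = HyperParams(beta=1.3, center=SYM)
        v1 = posterior_variance_information(c, h)
        v2 = posterior_variance_information(dup, h)
        assert v2 == pytest.approx(v1 / 2, rel=1e-9)

    def test_variance_vanishes_at_large_beta(self, balanced_table):
        h = HyperParams(beta=1e9, center=SYM)
        assert posterior_variance_information(balanced_table, h) < 1e-8
        assert posterior_variance_information(balanced_table, HyperParams(beta=np.inf, center=SYM)) == 0.0


class TestLogBetaPrior:
    def test_integrates_to_one(self):
        for center in ([0.5, 0.5], [0.25, 0.75], [0.2, 0.3, 0.5]):
            val, _ = quad(
                lambda lb: np.exp(log_beta_prior(np.exp(lb), center)), -25, 25, limit=200
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_positive_density_everywhere(self):
        for b in np.geomspace(1e-6, 1e6, 30):
            assert np.isfinite(log_beta_prior(float(b), SYM))

    def test_matches_finite_difference_of_prior_information(self):
        b = 1.0
        eps = 1e-6
        f = lambda lb: prior_mean_information(HyperParams(beta=np.exp(lb), center=SYM))
        deriv = (f(np.log(b) + eps) - f(np.log(b) - eps)) / (2 * eps)
        expected = abs(deriv) / np.log(2)
        assert np.exp(log_beta_prior(b, SYM)) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            log_beta_prior(0.0, SYM)


class TestAlphaInference:
    def test_doubleton_favors_small_alpha(self):
        c = counts_from_samples([("a", 0), ("a", 1)])
        grid = np.geomspace(1e-2, 1e8, 50)
        ll = log_marginal_likelihood_alpha(c, grid)
        assert np.all(np.diff(ll) < 0)
        a, diverged = alpha_map(c)
        assert a == pytest.approx(1e-2) and not diverged

    def test_two_singletons_diverge(self):
        c = counts_from_samples([("a", 0), ("b", 1)])
        grid = np.geomspace(1e-2, 1e4, 50)  # larger alphas hit float cancellation
        ll = log_marginal_likelihood_alpha(c, grid)
        assert np.all(np.diff(ll) > 0)
        a, diverged = alpha_map(c)
        assert diverged

    def test_recovers_dp_concentration_from_samples(self):
        # N=40 draws from a DP(alpha=e^5) marginal; the sampler here is the
        # Chinese-restaurant process, independent of the package's
        # stick-breaking route.  Median MAP within a factor 3 of truth.
        truth = float(np.exp(5))
        gen = np.random.default_rng(99)
        ratios = []
        for _ in range(100):
            labels = []
            for i in range(40):
                if gen.random() < truth / (truth + i):
                    labels.append(len(labels))  # new state
                else:
                    labels.append(int(gen.integers(len(labels))))
            pairs = [(x, int(gen.integers(2))) for x in labels]
            a, diverged = alpha_map(counts_from_samples(pairs))
            if not diverged:
                ratios.append(a / truth)
        assert 1 / 3 < np.median(ratios) < 3


class TestDPCorrectedMean:
    def test_alpha_limits(self, balanced_table):
        c = balanced_table
        base = HyperParams(beta=1.5, center=SYM)
        post = posterior_mean_information(c, base)
        prior = prior_mean_information(base)
        tiny = posterior_mean_information_dp(c, HyperParams(beta=1.5, center=SYM, alpha=1e-12))
        huge = posterior_mean_information_dp(c, HyperParams(beta=1.5, center=SYM, alpha=1e14))
        assert tiny == pytest.approx(post, abs=1e-10)
        assert huge == pytest.approx(prior, abs=1e-10)

    def test_alpha_equal_n_is_midpoint(self, balanced_table):
        c = balanced_table
        h = HyperParams(beta=1.5, center=SYM, alpha=float(c.N))
        mid = posterior_mean_information_dp(c, h)
        expected = 0.5 * (
            posterior_mean_information(c, HyperParams(beta=1.5, center=SYM))
            + prior_mean_information(HyperParams(beta=1.5, center=SYM))
        )
        assert mid == pytest.approx(expected, rel=1e-12)


class TestEstimate:
    def test_independent_data_give_small_information(self, rng):
        xs = rng.integers(0, 50, size=2000)
        ys = rng.integers(0, 2, size=2000)
        s = estimate(counts_from_samples(list(zip(xs.tolist(), ys.tolist()))))
        assert s.I_mean < 0.02

    def test_deterministic_relation_approaches_hy(self):
        prev = 0.0
        for reps in (2, 4, 8, 16):
            pairs = [(f"x{i}", i % 2) for i in range(10) for _ in range(reps)]
            s = estimate(counts_from_samples(pairs))
            assert prev < s.I_mean <= s.HY_hat + 1e-9
            prev = s.I_mean
        assert prev > 0.55  # close to log 2 by 16 repeats

    def test_integration_mandatory_with_few_coincidences(self):
        pairs = [(f"x{i}", i % 2) for i in range(12)] + [("c0", 0), ("c0", 1)]
        s = estimate(counts_from_samples(pairs))
        assert s.method == "integrate"
        assert s.I_sd > 0

    def test_multiplicity_sufficiency(self):
        # same multiplicity sets -> identical likelihood curve and estimate
        p1 = [("p0", 0), ("p0", 1), ("p1", 0), ("p1", 1),
              ("d0", 0), ("d0", 0), ("d1", 0), ("d1", 0),
              ("d2", 1), ("d2", 1), ("d3", 1), ("d3", 1),
              ("s0", 0), ("s1", 1)]
        # same patterns, different labels and different y assignments
        p2 = [("q0", 1), ("q0", 0), ("q1", 0), ("q1", 1),
              ("e0", 1), ("e0", 1), ("e1", 0), ("e1", 0),
              ("e2", 0), ("e2", 0), ("e3", 1), ("e3", 1),
              ("z0", 1), ("z1", 0)]
        t1, t2 = counts_from_samples(p1), counts_from_samples(p2)
        m1, m2 = multiplicities_from_counts(t1), multiplicities_from_counts(t2)
        assert m1.table == m2.table
        s1, s2 = estimate(t1), estimate(t2)
        np.testing.assert_allclose(s1.beta_loglike - s1.beta_loglike[0],
                                   s2.beta_loglike - s2.beta_loglike[0], atol=1e-9)
        assert s1.I_mean == pytest.approx(s2.I_mean, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nonnegative_and_bounded_by_hy(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 60))
        k = int(gen.integers(2, 20))
        xs = gen.integers(0, k, size=n)
        ys = gen.integers(0, 2, size=n)
        s = estimate(counts_from_samples(list(zip(xs.tolist(), ys.tolist()))))
        assert s.I_mean >= -1e-9
        assert s.I_mean <= s.HY_hat + 1e-9
        assert s.I_sd >= 0

    def test_independence_bias_halves_with_sample_size(self):
        # under independence the bias decays like 1/N once coincidences are
        # plentiful (pairwise coincidences grow like N^2 for uniform q_x)
        def mean_est(n, reps=30):
            vals = []
            for r in range(reps):
                g = np.random.default_rng(4000 + r)
                xs = g.integers(2000, size=n)
                ys = g.integers(2, size=n)
                vals.append(estimate(counts_from_samples(list(zip(xs.tolist(), ys.tolist())))).I_mean)
            return float(np.mean(vals))

        b400, b800 = mean_est(400), mean_est(800)
        assert b800 < b400
        assert 1.3 < b400 / b800 < 3.0

    def test_units_bits_conversion(self, balanced_table):
        s_nats = estimate(balanced_table, method="map")
        s_bits = estimate(balanced_table, method="map", units="bits")
        assert s_bits.I_mean == pytest.approx(s_nats.I_mean / np.log(2), rel=1e-12)
        assert s_bits.HY_hat == pytest.approx(1.0, rel=1e-12)

    def test_ky_one_returns_zero_with_warning(self):
        c = counts_from_samples([("a", 0), ("b", 0), ("b", 0)])
        s = estimate(c)
        assert s.I_mean == 0.0
        assert any("k_y = 1" in w for w in s.warnings)
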