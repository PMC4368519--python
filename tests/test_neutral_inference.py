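import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from sadpower.neutral_inference import (
    AbundanceSample,
    _log_conv,
    _log_conv_naive,
    etienne_log_likelihood,
    maximize_likelihood,
    urn_sample,
)
from conftest import integer_partitions


def sample_probability(counts, theta, m):
    return math.exp(etienne_log_likelihood(AbundanceSample.from_counts(counts),
                                           theta, m))


class TestLikelihood:
    def test_single_individual_is_certain(self):
        D = AbundanceSample.from_counts([1])
        for theta, m in [(0.1, 0.01), (5.0, 0.9), (100.0, 0.5)]:
            assert etienne_log_likelihood(D, theta, m) == 0.0

    def test_two_individual_enumeration(self):
        # brute-force urn enumeration at J=2, theta=1, I=1:
        # P(one doubleton) = 3/4, P(two singletons) = 1/4
        assert sample_probability([2], 1.0, 0.5) == pytest.approx(0.75, abs=1e-12)
        assert sample_probability([1, 1], 1.0, 0.5) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("theta,m", [(2.0, 0.3), (0.5, 0.9), (10.0, 0.05)])
    def test_normalization_over_all_configurations(self, theta, m):
        for J in (4, 5, 6):
            total = sum(sample_probability(p, theta, m)
                        for p in integer_partitions(J))
            assert math.log(total) == pytest.approx(0.0, abs=1e-10)

    def test_ewens_limit_at_m_equal_one(self):
        # m=1 is a pure metacommunity sample: Ewens sampling formula
        # P(single doubleton | theta) = 1/(1+theta), P(two singletons) =
        # theta/(1+theta)
        theta = 3.0
        assert sample_probability([2], theta, 1.0) == pytest.approx(
            1 / (1 + theta), abs=1e-12)
        assert sample_probability([1, 1], theta, 1.0) == pytest.approx(
            theta / (1 + theta), abs=1e-12)

    def test_label_invariance(self, rng):
        D = urn_sample(8.0, 0.4, 60, rng)
        shuffled = rng.permutation(D.counts)
        a = etienne_log_likelihood(D, 3.0, 0.2)
        b = etienne_log_likelihood(AbundanceSample(shuffled), 3.0, 0.2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_log_likelihood_is_nonpositive(self, rng):
        for _ in range(5):
            D = urn_sample(20.0, 0.3, 100, rng)
            assert etienne_log_likelihood(D, 7.0, 0.25) <= 0.0

    def test_parameter_errors(self):
        D = AbundanceSample.from_counts([3, 1])
        with pytest.raises(ValueError):
            etienne_log_likelihood(D, -1.0, 0.5)
        with pytest.raises(ValueError):
            etienne_log_likelihood(D, 2.0, 0.0)
        with pytest.raises(ValueError):
            etienne_log_likelihood(D, 2.0, 1.5)


class TestLogConvolution:
    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_segmented_matches_naive(self, seed):
        # the chunk-rescaled linear-space product must agree with plain
        # log-space convolution across extreme dynamic ranges
        r = np.random.default_rng(seed)
        a = np.sort(r.normal(0, 300, r.integers(2, 200)))[::-1].copy()
        b = r.normal(0, 150, r.integers(2, 120))
        ref = _log_conv_naive(a, b)
        np.testing.assert_allclose(_log_conv(a.copy(), b.copy()), ref,
                                   rtol=0, atol=1e-9)


class TestUrnSampler:
    def test_single_individual(self, rng):
        D = urn_sample(2.0, 0.5, 1, rng)
        assert D.counts.tolist() == [1]

    def test_two_species_fraction_at_J2(self, rng):
        n, reps = 0, 30_000
        for _ in range(reps):
            n += urn_sample(1.0, 0.5, 2, rng).S == 2
        se = math.sqrt(0.25 * 0.75 / reps)
        assert abs(n / reps - 0.25) < 3 * se

    def test_frequencies_match_likelihood(self, rng):
        # cross-validation of sampler vs exact likelihood at J=4
        theta, m, J, reps = 2.0, 0.3, 4, 30_000
        parts = list(integer_partitions(J))
        probs = np.array([sample_probability(p, theta, m) for p in parts])
        counts = dict.fromkeys(parts, 0)
        for _ in range(reps):
            counts[tuple(urn_sample(theta, m, J, rng).counts)] += 1
        observed = np.array([counts[p] for p in parts])
        res = chisquare(observed, probs * reps)
        assert res.pvalue > 0.01

    def test_subsampling_consistency(self, rng):
        # the urn scheme is exchangeable and consistent in J at fixed I:
        # a hypergeometric subsample of size J' from a sample at (theta, I)
        # has the law of a direct draw at (theta, m') with
        # I = m'(J'-1)/(1-m')
        theta, m, J, Jp, reps = 1.5, 0.4, 6, 3, 30_000
        I = m * (J - 1) / (1 - m)
        m_sub = I / (I + Jp - 1)
        parts = list(integer_partitions(Jp))
        direct = np.array([sample_probability(p, theta, m_sub) for p in parts])
        counts = dict.fromkeys(parts, 0)
        for _ in range(reps):
            big = urn_sample(theta, m, J, rng)
            pool = np.repeat(np.arange(big.S), big.counts)
            sub = pool[rng.choice(J, size=Jp, replace=False)]
            key = tuple(sorted(np.bincount(sub)[np.bincount(sub) > 0],
                               reverse=True))
            counts[key] += 1
        observed = np.array([counts[p] for p in parts])
        res = chisquare(observed, direct * reps)
        assert res.pvalue > 0.01

    def test_parameter_errors(self, rng):
        with pytest.raises(ValueError):
            urn_sample(0.0, 0.5, 10, rng)
        with pytest.raises(ValueError):
            urn_sample(1.0, 0.5, 0, rng)


class TestMaximizeLikelihood:
    def test_optimum_dominates_grid_starts(self, rng):
        D = urn_sample(30.0, 0.2, 150, rng)
        fit = maximize_likelihood(D)
        assert fit.logL_max >= fit.metadata["grid_best_logL"] - 1e-9
        assert fit.logL_max <= 0.0
        assert fit.converged

    def test_parameter_recovery(self, rng):
        # urn data at (theta=50, m=0.1, J=1000): medians across replicates
        # recover theta within 20% and m within a factor of 2
        thetas, ms = [], []
        for _ in range(100):
            D = urn_sample(50.0, 0.1, 1000, rng)
            fit = maximize_likelihood(D)
            thetas.append(fit.theta_hat)
            ms.append(fit.m_hat)
        assert abs(np.median(thetas) - 50.0) < 10.0
        assert 0.05 < np.median(ms) < 0.2

    def test_monodominant_sample_is_driven_to_boundary(self):
        # a single-species sample is most likely as m -> 0 (or theta -> 0)
        D = AbundanceSample.from_counts([200])
        fit = maximize_likelihood(D)
        assert fit.at_boundary
        assert fit.m_hat < 1e-3 or fit.theta_hat < 1e-2
        # and the likelihood approaches certainty at the boundary
        assert fit.logL_max > math.log(0.9)

    def test_degenerate_single_individual(self):
        fit = maximize_likelihood(AbundanceSample.from_counts([1]))
        assert fit.logL_max == 0.0


class TestAbundanceSample:
    def test_invariants(self):
        D = AbundanceSample.from_counts([1, 4, 3, 1])
        assert D.J == 9
        assert D.S == 4
        assert D.counts.tolist() == [4, 3, 1, 1]
        phi = D.phi
        assert phi[1] == 2 and phi[3] == 1 and phi[4] == 1
        assert (np.arange(phi.size) * phi).sum() == D.J
        assert phi.sum() == D.S

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            AbundanceSample.from_counts([])
        with pytest.raises(ValueError):
            AbundanceSample.from_counts([3, 0])
        with pytest.raises(ValueError):
            AbundanceSample.from_counts([-1, 2])
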