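import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from sadpower.local_dynamics import (
    BurnInPolicy,
    ConvergenceError,
    HLParams,
    IFParams,
    LocalCommunityState,
    PCParams,
    _hl_immigrant_prob,
    hl_mortality_weights,
    hl_params_from_rates,
    hl_step,
    if_assign_fitnesses,
    if_kinf_even_probs,
    if_propagule_fractions,
    if_step,
    pc_critical_scaled_c,
    pc_mean_map,
    pc_propagule_fractions,
    pc_step,
    pc_uniform_fixed_point_stable,
    run_to_equilibrium,
)
from sadpower.metacommunity import (
    even_metacommunity,
    infinite_even_metacommunity,
    sample_logseries_metacommunity,
)


class TestHLMortality:
    def test_neutral_limit_weights_proportional_to_abundance(self):
        st_ = LocalCommunityState({1: 3, 2: 7}, J=10)
        w = hl_mortality_weights(st_, gamma=0.0)
        assert w[1] == pytest.approx(0.3)
        assert w[2] == pytest.approx(0.7)

    def test_full_density_dependence(self):
        # gamma=1: unnormalized (n/J)^2 = {0.09, 0.49} -> {9/58, 49/58}
        st_ = LocalCommunityState({1: 3, 2: 7}, J=10)
        w = hl_mortality_weights(st_, gamma=1.0)
        assert w[1] == pytest.approx(9 / 58)
        assert w[2] == pytest.approx(49 / 58)

    def test_single_species_normalizes_to_one(self):
        st_ = LocalCommunityState({5: 20}, J=20)
        for gamma in (0.0, 0.33, 1.0):
            assert hl_mortality_weights(st_, gamma)[5] == pytest.approx(1.0)

    def test_gamma_out_of_range(self):
        st_ = LocalCommunityState({1: 2}, J=2)
        with pytest.raises(ValueError):
            hl_mortality_weights(st_, 1.2)
        with pytest.raises(ValueError):
            HLParams(gamma=-0.1, m=0.5)


class TestHLRateMapping:
    def test_alpha_one_is_neutral(self):
        p = hl_params_from_rates(2.0, 1.0, 100.0, 1.0, 5.0, 100, 10)
        assert p.gamma == 0.0

    def test_large_mu_gives_full_immigration(self):
        p = hl_params_from_rates(2.0, 1.0, 100.0, 0.5, 1e12, 100, 10)
        assert p.m == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_oracle(self):
        # independent hand evaluation at
        # (r+=2, r-=1, K'=100, alpha=0.5, J=100, S_T=10, mu=5)
        r_p, r_m, K, a, J, S_T, mu = 2.0, 1.0, 100.0, 0.5, 100, 10, 5.0
        bracket = (r_m * K + (r_p - r_m) * J * a) / ((r_p - r_m) * J * (1 - a))
        gamma_expect = 1.0 / (1.0 + bracket)          # = 1/4
        m_expect = 1.0 / (1.0 + r_p * J / (mu * S_T))  # = 1/5
        p = hl_params_from_rates(r_p, r_m, K, a, mu, J, S_T)
        assert p.gamma == pytest.approx(gamma_expect)
        assert gamma_expect == pytest.approx(0.25)
        assert p.m == pytest.approx(m_expect)
        assert m_expect == pytest.approx(0.2)

    def test_rate_ordering_required(self):
        with pytest.raises(ValueError):
            hl_params_from_rates(1.0, 2.0, 100.0, 0.5, 5.0, 100, 10)

    def test_strongly_mutualistic_alpha_rejected(self):
        with pytest.raises(ValueError):
            hl_params_from_rates(2.0, 1.0, 100.0, -50.0, 5.0, 100, 10)


class TestHLMarkovChainOracle:
    def test_stationary_distribution_of_tiny_community(self, rng):
        # J=3, S_T=2 EVEN, m=0.5, gamma=0.5: the abundance n_1 of species 1
        # is a 4-state Markov chain whose stationary law we solve exactly
        J, m, gamma = 3, 0.5, 0.5
        p_imm = _hl_immigrant_prob(m, J)

        def death_probs(n1):
            w1 = ((1 - gamma) + gamma * n1 / J) * n1
            w2 = ((1 - gamma) + gamma * (J - n1) / J) * (J - n1)
            return w1 / (w1 + w2)

        # one elemental step: death then recruitment from survivors/meta
        P = np.zeros((J + 1, J + 1))
        for n1 in range(J + 1):
            for sp1_dies in (True, False):
                pd = death_probs(n1) if sp1_dies else 1 - death_probs(n1)
                if pd == 0:
                    continue
                n1p = n1 - 1 if sp1_dies else n1
                p_recruit1 = p_imm * 0.5 + (1 - p_imm) * n1p / (J - 1)
                P[n1, n1p + 1] += pd * p_recruit1
                P[n1, n1p] += pd * (1 - p_recruit1)
        evals, evecs = np.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()

        meta = even_metacommunity(2)
        state = LocalCommunityState({1: 2, 2: 1}, J=J)
        occup = np.zeros(J + 1)
        params = HLParams(gamma=gamma, m=m)
        for _ in range(4000):
            state = hl_step(state, params, meta, rng)
            occup[state.counts.get(1, 0)] += 1
        occup /= occup.sum()
        assert np.abs(occup - stat).max() < 0.03


class TestPCFractions:
    def test_neutral_limit(self):
        st_ = LocalCommunityState({1: 10, 2: 90}, J=100)
        L = pc_propagule_fractions(st_, c=0.0)
        assert L[1] == pytest.approx(0.1)
        assert L[2] == pytest.approx(0.9)

    def test_equal_abundances_cancel_for_any_c(self):
        st_ = LocalCommunityState({i: 20 for i in range(1, 6)}, J=100)
        for c in (0.0, 1.0, 7.0):
            L = pc_propagule_fractions(st_, c)
            for v in L.values():
                assert v == pytest.approx(0.2)

    def test_direct_evaluation(self):
        st_ = LocalCommunityState({1: 10, 2: 90}, J=100)
        L = pc_propagule_fractions(st_, c=1.0)
        num = 10 * math.exp(-0.1)
        den = num + 90 * math.exp(-0.9)
        assert L[1] == pytest.approx(num / den)


class TestSynchronousSteps:
    def test_pc_full_immigration_is_metacommunity_multinomial(self, rng):
        # m=1: the new configuration is multinomial(J, P) exactly
        meta = even_metacommunity(5)
        params = PCParams(c=3.0, m=1.0)
        state = LocalCommunityState({1: 50}, J=50)
        pooled = np.zeros(5)
        reps = 400
        for _ in range(reps):
            new = pc_step(state, params, meta, rng)
            for s, n in new.counts.items():
                pooled[s - 1] += n
        res = chisquare(pooled, np.full(5, 50 * reps / 5))
        assert res.pvalue > 0.01

    def test_if_equals_pc_in_neutral_limit_distribution(self, rng):
        # k=0 fitnesses are all equal, so R_i = mP_i + (1-m) n_i/J for both
        meta = even_metacommunity(4)
        state = LocalCommunityState({1: 30, 2: 10}, J=40)
        fit = if_assign_fitnesses(4, 0.0, rng)
        assert set(fit.values()) == {1.0}
        pooled_if = np.zeros(4)
        pooled_pc = np.zeros(4)
        for _ in range(600):
            a = if_step(state, IFParams(k=0.0, m=0.3, fitnesses=fit), meta, rng)
            b = pc_step(state, PCParams(c=0.0, m=0.3), meta, rng)
            for s, n in a.counts.items():
                pooled_if[s - 1] += n
            for s, n in b.counts.items():
                pooled_pc[s - 1] += n
        res = chisquare(pooled_if, pooled_pc * pooled_if.sum() / pooled_pc.sum())
        assert res.pvalue > 0.01

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_community_size_conserved(self, seed):
        r = np.random.default_rng(seed)
        J = int(r.integers(2, 60))
        meta = (sample_logseries_metacommunity(5.0, 30, r)
                if r.random() < 0.5 else even_metacommunity(10))
        n = r.multinomial(J, meta.rel_abundance)
        state = LocalCommunityState(
            {i + 1: int(v) for i, v in enumerate(n) if v > 0}, J=J)
        m = float(r.uniform(0.05, 1.0))
        out_pc = pc_step(state, PCParams(c=float(r.uniform(0, 2)), m=m), meta, r)
        assert sum(out_pc.counts.values()) == J
        fits = if_assign_fitnesses(int(meta.S_T), 0.5, r)
        out_if = if_step(state, IFParams(k=0.5, m=m, fitnesses=fits), meta, r)
        assert sum(out_if.counts.values()) == J
        out_hl = hl_step(state, HLParams(gamma=float(r.uniform(0, 1)), m=m),
                         meta, r)
        assert sum(out_hl.counts.values()) == J


class TestIFFitnesses:
    def test_zero_k_means_identical_fitnesses(self, rng):
        assert set(if_assign_fitnesses(50, 0.0, rng).values()) == {1.0}

    def test_coefficient_of_variation(self, rng):
        f = np.array(list(if_assign_fitnesses(100_000, 0.25, rng).values()))
        cv = f.std() / f.mean()
        assert cv == pytest.approx(0.5, abs=0.02)

    def test_scale_invariance_of_fractions(self):
        state = LocalCommunityState({1: 5, 2: 15}, J=20)
        f = {1: 0.3, 2: 1.2}
        f7 = {s: 7 * v for s, v in f.items()}
        a = if_propagule_fractions(state, f)
        b = if_propagule_fractions(state, f7)
        for s in a:
            assert a[s] == pytest.approx(b[s], rel=1e-12)

    def test_negative_k_rejected(self, rng):
        with pytest.raises(ValueError):
            if_assign_fitnesses(10, -0.5, rng)

    def test_missing_fitness_is_an_error(self, rng):
        state = LocalCommunityState({1: 5, 2: 5}, J=10)
        meta = even_metacommunity(2)
        with pytest.raises(RuntimeError):
            if_step(state, IFParams(k=1.0, m=0.5, fitnesses={1: 1.0}), meta, rng)


class TestPCStability:
    @pytest.mark.parametrize("S_T", [2, 10, 50])
    def test_flip_bifurcation_at_scaled_strength_two(self, S_T):
        # stable just below c/S_T = 2, unstable just above
        assert pc_uniform_fixed_point_stable(1.9 * S_T, S_T)
        assert not pc_uniform_fixed_point_stable(2.1 * S_T, S_T)

    def test_located_threshold(self):
        assert pc_critical_scaled_c(10, tol=1e-4) == pytest.approx(2.0, abs=1e-3)

    def test_mean_map_preserves_simplex(self):
        r = np.array([0.2, 0.3, 0.5])
        out = pc_mean_map(r, 1.3)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out > 0)

    def test_unstable_regime_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            PCParams(c=50.0, m=0.1).check_stability(S_T=10)


class TestEquilibration:
    def test_if_kinf_even_matches_closed_form_composition(self, rng):
        m, S_T, J = 0.1, 50, 300
        meta = even_metacommunity(S_T)
        fit = {s: 0.0 for s in range(1, S_T + 1)}
        fit[1] = 1.0
        params = IFParams(k=math.inf, m=m, fitnesses=fit)
        state = LocalCommunityState({1: J}, J=J)
        pooled = np.zeros(S_T)
        reps = 60
        for _ in range(reps):
            for _ in range(3):
                state = if_step(state, params, meta, rng)
            for s, n in state.counts.items():
                pooled[s - 1] += n
        expected = if_kinf_even_probs(m, S_T) * J * reps
        res = chisquare(pooled, expected)
        assert res.pvalue > 0.01

    def test_monodominance_strengthens_with_k(self, rng):
        # mean equilibrium richness is non-increasing in k (EVEN meta)
        mean_S = []
        for k in (0.0, 0.5, 8.0):
            Ss = [
                run_to_equilibrium(
                    "IF", IFParams(k=k, m=0.05), even_metacommunity(50),
                    200, rng,
                ).S
                for _ in range(20)
            ]
            mean_S.append(np.mean(Ss))
        assert mean_S[1] <= mean_S[0] + 1.0
        assert mean_S[2] <= mean_S[1] + 1.0
        assert mean_S[2] < mean_S[0]

    def test_full_immigration_equilibrates_to_metacommunity_sample(self, rng):
        meta = even_metacommunity(20)
        s = run_to_equilibrium("PC", PCParams(c=1.0, m=1.0), meta, 100, rng)
        # composition ~ multinomial(J, 1/20): richness near 20
        assert s.S > 15
        assert s.metadata["steps_run"] < 2000

    def test_burn_in_cap_raises(self, rng):
        meta = sample_logseries_metacommunity(20.0, 200, rng)
        policy = BurnInPolicy(max_steps=30, window=50)
        with pytest.raises(ConvergenceError):
            run_to_equilibrium("PC", PCParams(c=0.0, m=0.1), meta, 100, rng,
                               burn_in_policy=policy)

    def test_sample_metadata_records_run(self, rng):
        meta = even_metacommunity(10)
        s = run_to_equilibrium("PC", PCParams(c=0.5, m=0.5), meta, 50, rng)
        md = s.metadata
        assert md["model"] == "PC"
        assert md["steps_run"] == 10 * md["burn_in_detected"]
        assert s.J == 50
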