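import numpy as np
import pytest

from interdep import (DynamicsParams, Ecology, PopulationState, compute_stats,
                      cooperation_increase, fermi_probability,
                      fixation_probabilities, pairwise_game_payoff,
                      payoff_matrix, state_payoffs, transition_probabilities)
from interdep.dynamics import StateSpace

from conftest import dense_absorption_oracle


class TestPairwisePayoffs:
    def test_fixed_behaviour_self_payoffs(self, pd_stats):
        assert pairwise_game_payoff("AllD", "AllD", pd_stats, 0.1) == 0.0
        assert pairwise_game_payoff("AllC", "AllC", pd_stats, 0.1) == 1.0

    def test_adaptive_self_payoff_in_harmony_ecology(self, harmony_stats):
        # alpha_plus = 1, so pi(AA, AA) = 1 - c
        assert pairwise_game_payoff("AA", "AA", harmony_stats, 0.1, "doc") == pytest.approx(0.9)

    def test_unknown_strategy_rejected(self, pd_stats):
        with pytest.raises(ValueError):
            pairwise_game_payoff("TitForTat", "AllC", pd_stats, 0.1)

    def test_payoff_table_cross_terms(self, pd_stats):
        M = payoff_matrix(pd_stats, 0.1, "doc")
        st = pd_stats
        assert M[2, 0] == pytest.approx(st.tplus)            # AllD vs AA
        assert M[1, 0] == pytest.approx(st.alpha_plus + st.sminus)
        assert M[0, 1] == pytest.approx(st.alpha_plus + st.tminus - 0.1)
        assert M[1, 2] == pytest.approx(st.mean_s)
        assert M[2, 1] == pytest.approx(st.mean_t)


class TestStatePayoffs:
    def test_monomorphic_populations(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        assert state_payoffs(PopulationState(0, 0, 60), params, "doc")["AllD"] == 0.0
        assert state_payoffs(PopulationState(0, 60, 0), params, "doc")["AllC"] == 1.0

    def test_lone_adaptive_agent_among_defectors(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        pi = state_payoffs(PopulationState(1, 0, 59), params, "doc")
        assert pi["AA"] == pytest.approx(pd_stats.splus - 0.1, abs=1e-12)

    def test_brute_force_partner_average(self, pd_stats):
        """Averaging the pairwise table over an explicit partner list."""
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        state = PopulationState(5, 12, 43)
        M = payoff_matrix(pd_stats, 0.1, "doc")
        partners = [0] * 4 + [1] * 12 + [2] * 43  # the other N-1 agents seen by an AA
        expected = np.mean([M[0, p] for p in partners])
        assert state_payoffs(state, params, "doc")["AA"] == pytest.approx(expected, abs=1e-12)

    def test_absent_strategy_payoff_is_undefined(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        assert state_payoffs(PopulationState(0, 30, 30), params, "doc")["AA"] is None


class TestFermi:
    def test_symmetric_cases(self):
        assert fermi_probability(1.3, 1.3, 5.0) == 0.5
        assert fermi_probability(2.0, -1.0, 0.0) == 0.5

    def test_strong_selection_limit(self):
        assert fermi_probability(1.0, 0.0, 1e6) == pytest.approx(1.0, abs=1e-12)
        assert fermi_probability(0.0, 1.0, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_numerical_stability_at_extreme_arguments(self):
        assert np.isfinite(fermi_probability(1e8, -1e8, 10.0))
        assert fermi_probability(-1e8, 1e8, 10.0) == 0.0


class TestTransitions:
    def test_absorbing_state_self_loop(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        probs = transition_probabilities(PopulationState(60, 0, 0), params, "doc")
        assert probs == {(60, 0, 0): 1.0}

    def test_neutral_transition_formula(self, pd_stats):
        params = DynamicsParams(beta=0.0, c=0.1, stats=pd_stats)
        state = PopulationState(10, 20, 30)
        probs = transition_probabilities(state, params, "doc")
        N = 60
        assert probs[(11, 19, 30)] == pytest.approx(10 * 20 / (2 * N * (N - 1)))
        assert probs[(9, 20, 31)] == pytest.approx(10 * 30 / (2 * N * (N - 1)))

    def test_normalisation(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        for state in [PopulationState(10, 20, 30), PopulationState(1, 1, 58),
                      PopulationState(0, 30, 30)]:
            probs = transition_probabilities(state, params, "doc")
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-14)

    def test_extinct_strategies_stay_extinct(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        probs = transition_probabilities(PopulationState(0, 25, 35), params, "doc")
        assert all(t[0] == 0 for t in probs)


class TestFixation:
    def test_neutral_drift_fixes_at_initial_frequencies(self, pd_stats):
        params = DynamicsParams(beta=0.0, c=0.1, stats=pd_stats)
        for init in [(20, 20, 20), (1, 10, 49), (30, 15, 15)]:
            res = fixation_probabilities(PopulationState(*init), params, "doc")
            for phi, n0 in zip(res.as_tuple(), init):
                assert phi == pytest.approx(n0 / 60, abs=1e-8)

    def test_dense_oracle_equivalence_small_populations(self, pd_stats):
        """Sparse chain solver vs dense enumeration at N <= 6."""
        rng = np.random.default_rng(0)
        for N in (3, 4, 5, 6):
            space = StateSpace(N)
            for _ in range(5):
                M = rng.normal(0.5, 0.8, (3, 3))
                beta = rng.uniform(0.0, 3.0)
                B = space.solve_absorption(M, beta, scale=1.0)
                ref, index = dense_absorption_oracle(M, N, beta, scale=1.0)
                for (x, y, z), i in index.items():
                    np.testing.assert_allclose(B[space.index(x, y)], ref[i], atol=1e-10)

    def test_conservation_across_random_parameters(self):
        rng = np.random.default_rng(4)
        space = StateSpace(12)
        for _ in range(100):
            M = rng.normal(0.0, 1.0, (3, 3))
            B = space.solve_absorption(M, rng.uniform(0, 5), scale=1.0)
            np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_fixation_declines_with_inference_cost(self):
        for (s0, t0) in [(-0.5, 0.5), (0.5, 1.5), (-0.5, 1.5)]:
            stats = compute_stats(Ecology(s0, t0, 2.0, m=100_000, seed=1), agent_kind="doc")
            prev = np.inf
            for c in [0.0, 0.1, 0.2, 0.3]:
                params = DynamicsParams(beta=1.0, c=c, stats=stats)
                phi = fixation_probabilities(PopulationState(20, 20, 20), params, "doc").phi_a
                assert phi <= prev + 1e-12
                prev = phi


class TestCooperationIncrease:
    def test_costfree_doc_equals_allc_in_harmony_ecology(self, harmony_stats):
        # alpha_plus = 1 and c = 0 make AA payoff-identical to AllC.  The
        # baseline starts from (0, 30, 30) while the merged cooperator types
        # start at 40/60, so the increase vanishes only up to the defectors'
        # (tiny) extra extinction odds against 30 rather than 40 cooperators.
        params = DynamicsParams(beta=1.0, c=0.0, stats=harmony_stats)
        inc = cooperation_increase(PopulationState(20, 20, 20), params, "doc")
        assert inc == pytest.approx(0.0, abs=1e-6)

    def test_costly_tog_cannot_help_in_harmony_ecology(self, harmony_stats):
        # up to the same baseline-composition residual as above
        params = DynamicsParams(beta=1.0, c=0.1, stats=harmony_stats)
        inc = cooperation_increase(PopulationState(20, 20, 20), params, "tog")
        assert inc <= 1e-6

    def test_doc_raises_cooperation_in_heterogeneous_pd(self, pd_stats):
        params = DynamicsParams(beta=1.0, c=0.1, stats=pd_stats)
        inc = cooperation_increase(PopulationState(20, 20, 20), params, "doc")
        assert inc > 0.0
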