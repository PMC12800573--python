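"""CTMC transition machinery and the pruning likelihood engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylolink.ctmc import (
    LOG_ZERO,
    PruningEngine,
    RateMatrix2,
    RateMatrix4,
    stationary_distribution,
    tip_partials_for,
    transition_probabilities,
    tree_log_likelihood,
)
from phylolink.io import Phylogeny

from helpers import brute_force_loglik, random_tree


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        P = transition_probabilities(RateMatrix2(0.7, 1.3), 0.0)
        assert np.allclose(P, np.eye(2))
        P4 = transition_probabilities(RateMatrix4(*([0.5] * 8)), 0.0)
        assert np.allclose(P4, np.eye(4))

    def test_two_state_closed_form(self):
        # symmetric rates 1, t = 0.5: P(stay) = (1 + e^-1)/2
        P = transition_probabilities(RateMatrix2(1.0, 1.0), 0.5)
        assert abs(P[0, 0] - (1 + np.exp(-1)) / 2) < 1e-12

    def test_long_time_reaches_stationary(self):
        Q = RateMatrix2(0.3, 0.9)
        P = transition_probabilities(Q, 500.0)
        for row in P:
            assert np.allclose(row, Q.stationary(), atol=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(RateMatrix2(1, 1), -0.1)

    @given(
        rates=st.lists(st.floats(1e-4, 50.0), min_size=8, max_size=8),
        t=st.floats(0.0, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_four_state_rows_stochastic(self, rates, t):
        P = transition_probabilities(RateMatrix4(*rates), t)
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_four_state_matches_expm(self):
        from scipy.linalg import expm

        Q = RateMatrix4(0.1, 2.0, 0.4, 1.1, 3.0, 0.2, 0.8, 0.05)
        for t in (0.01, 0.3, 2.5):
            assert np.allclose(
                transition_probabilities(Q, t), expm(Q.to_generator() * t), atol=1e-9
            )


class TestGenerators:
    def test_generator_rows_sum_to_zero(self):
        for Q in (RateMatrix2(0.2, 3.0), RateMatrix4(*np.arange(1, 9) * 0.3)):
            assert np.allclose(Q.to_generator().sum(axis=1), 0.0)

    def test_independent_embedding(self):
        a, b = RateMatrix2(0.1, 1.0), RateMatrix2(0.5, 2.0)
        Q = RateMatrix4.independent(a, b)
        assert Q.alpha1 == Q.alpha2 == a.q01
        assert Q.gamma1 == Q.gamma2 == a.q10
        assert Q.beta1 == Q.beta2 == b.q01
        assert Q.delta1 == Q.delta2 == b.q10

    def test_stationary_uniform_for_symmetric_rates(self):
        Q = RateMatrix4(*([0.7] * 8))
        pi, reducible = stationary_distribution(Q.to_generator())
        assert not reducible
        assert np.allclose(pi, 0.25)


class TestPruning:
    def test_zero_branches_force_root_equal_tips(self):
        tree = Phylogeny.from_newick("(A:0,B:0);")
        ll = tree_log_likelihood(tree, {"A": 1, "B": 1}, RateMatrix2(1, 1))
        assert abs(ll - np.log(0.5)) < 1e-12

    def test_zero_rates_discordant_tips_log_zero(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        ll = tree_log_likelihood(tree, {"A": 0, "B": 1}, RateMatrix2(0.0, 0.0))
        assert ll == LOG_ZERO

    def test_missing_tip_state_raises(self, balanced4):
        with pytest.raises(Exception, match="D"):
            tree_log_likelihood(balanced4, {"A": 1, "B": 0, "C": 1},
                                RateMatrix2(1, 1))

    @pytest.mark.parametrize("n_states", [2, 4])
    def test_pruning_equals_brute_force(self, rng, n_states):
        """Dynamic-programming likelihood equals exhaustive summation over
        internal states on every small random tree."""
        for trial in range(25):
            n = int(rng.integers(3, 7))
            tree = random_tree(rng, n)
            if n_states == 2:
                Q = RateMatrix2(*np.exp(rng.uniform(-2.5, 1.5, 2)))
            else:
                Q = RateMatrix4(*np.exp(rng.uniform(-2.5, 1.5, 8)))
            states = rng.integers(0, n_states, n)
            prior = np.full(n_states, 1.0 / n_states)
            a = tree_log_likelihood(tree, states, Q)
            b = brute_force_loglik(tree, states, Q, prior)
            assert abs(a - b) <= 1e-8, (trial, a, b)

    def test_kernel_and_numpy_paths_agree(self, rng):
        tree = random_tree(rng, 10)
        Q = RateMatrix4(*np.exp(rng.uniform(-2, 1, 8)))
        states = rng.integers(0, 4, 10)
        partials = tip_partials_for(tree, states, 4)
        prior = np.full(4, 0.25)
        fast = PruningEngine(tree, 4, use_kernel=True)
        slow = PruningEngine(tree, 4, use_kernel=False)
        assert abs(fast.loglik(partials, Q, prior)
                   - slow.loglik(partials, Q, prior)) < 1e-9

    def test_child_order_invariance(self, rng):
        nwk_a = "((A:1,B:2):0.5,(C:0.7,D:1.2):0.3);"
        nwk_b = "((D:1.2,C:0.7):0.3,(B:2,A:1):0.5);"
        Q = RateMatrix2(0.4, 1.7)
        states = {"A": 1, "B": 0, "C": 1, "D": 0}
        la = tree_log_likelihood(Phylogeny.from_newick(nwk_a), states, Q)
        lb = tree_log_likelihood(Phylogeny.from_newick(nwk_b), states, Q)
        assert abs(la - lb) < 1e-12

    def test_rescaling_invariance(self, rng):
        """Multiplying branch lengths by c and dividing rates by c leaves
        the likelihood unchanged."""
        tree = random_tree(rng, 8)
        states = rng.integers(0, 2, 8)
        Q = RateMatrix2(0.3, 1.1)
        c = 3.7
        l0 = tree_log_likelihood(tree, states, Q)
        l1 = tree_log_likelihood(
            tree.rescaled(c), states, RateMatrix2(0.3 / c, 1.1 / c)
        )
        assert abs(l0 - l1) < 1e-8

    def test_multifurcating_tree_likelihood(self, rng):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1,(D:0.5,E:0.5):0.5);")
        Q = RateMatrix2(0.5, 0.5)
        states = np.array([1, 0, 1, 0, 1])
        a = tree_log_likelihood(tree, dict(zip(sorted(tree.tip_labels), states)), Q)
        order = [sorted(tree.tip_labels).index(lab) for lab in tree.tip_labels]
        b = brute_force_loglik(tree, states[order], Q, np.array([0.5, 0.5]))
        assert abs(a - b) < 1e-9
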