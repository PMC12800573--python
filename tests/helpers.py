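"""Shared test helpers: the brute-force likelihood oracle and random trees."""

from __future__ import annotations

from itertools import product

import numpy as np

from phylolink.ctmc import transition_probabilities
from phylolink.io import Phylogeny


def brute_force_loglik(tree: Phylogeny, tip_states, Q, prior) -> float:
    """Likelihood by explicit summation over all internal-node state
    assignments — exponential, usable only on tiny trees, and entirely
    independent of the pruning implementation."""
    S = Q.n_states
    P = {
        v: transition_probabilities(Q, float(tree.edge_length[v]))
        for v in range(tree.n_nodes)
    }
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    tips = {int(t): int(s) for t, s in zip(tree.tips, tip_states)}
    total = 0.0
    for assign in product(range(S), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tips)
        lik = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                lik *= P[v][st[p], st[v]]
        total += lik
    return np.log(total) if total > 0 else -np.inf


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random topology with random branch lengths."""
    from phylolink.simulate import simulate_tree

    tree = simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    lengths = tree.edge_length.copy()
    lengths[1:] = rng.uniform(0.05, 2.0, size=lengths.size - 1)
    return Phylogeny(tree.parent, lengths, tree.labels)
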