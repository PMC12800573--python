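"""Continuous-time Markov chains for binary traits and trait pairs on a tree.

Two generators are supported: a 2-state chain for a single binary trait
(gain rate ``q01``, loss rate ``q10``) and a 4-state chain for an ordered
trait pair over states ``(0,0), (0,1), (1,0), (1,1)`` in which each trait's
gain/loss rate may depend on the current state of the partner trait
(dual-change rates are fixed at 0).  Likelihoods are computed by pruning
(postorder accumulation of partial likelihoods) with per-node rescaling to
avoid underflow; transition matrices come from the closed-form 2-state
solution or an eigendecomposition of the 4-state generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import _kernels
from .io import Phylogeny, PhylolinkError

__all__ = [
    "RateMatrix2",
    "RateMatrix4",
    "transition_probabilities",
    "tree_log_likelihood",
    "stationary_distribution",
    "PruningEngine",
    "LOG_ZERO",
]

# sentinel for log(0) likelihood (all-rates-zero with discordant tips, etc.)
LOG_ZERO = -1e308

PAIR_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class RateMatrix2:
    """2-state generator for one binary trait: gain ``q01`` (0→1), loss ``q10`` (1→0)."""

    q01: float
    q10: float

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_states(self) -> int:
        return 2

    def to_generator(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])

    def stationary(self) -> np.ndarray:
        tot = self.q01 + self.q10
        if tot == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10, self.q01]) / tot


@dataclass(frozen=True)
class RateMatrix4:
    """4-state generator for a trait pair (A, B) over states 00, 01, 10, 11.

    ``alpha1 = q(00→10)``, ``alpha2 = q(01→11)`` — gain of A without/with B;
    ``beta1 = q(00→01)``, ``beta2 = q(10→11)`` — gain of B without/with A;
    ``gamma1 = q(10→00)``, ``gamma2 = q(11→01)`` — loss of A without/with B;
    ``delta1 = q(01→00)``, ``delta2 = q(11→10)`` — loss of B without/with A.
    Dual transitions (00↔11, 01↔10) have rate 0.  The independent submodel is
    the constraint alpha1=alpha2, beta1=beta2, gamma1=gamma2, delta1=delta2.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    gamma1: float
    gamma2: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates()):
            raise ValueError("rates must be >= 0")

    def rates(self) -> tuple[float, ...]:
        return (
            self.alpha1,
            self.alpha2,
            self.beta1,
            self.beta2,
            self.gamma1,
            self.gamma2,
            self.delta1,
            self.delta2,
        )

    @classmethod
    def independent(cls, a: RateMatrix2, b: RateMatrix2) -> "RateMatrix4":
        """Pair generator for two independently evolving traits."""
        return cls(
            alpha1=a.q01,
            alpha2=a.q01,
            beta1=b.q01,
            beta2=b.q01,
            gamma1=a.q10,
            gamma2=a.q10,
            delta1=b.q10,
            delta2=b.q10,
        )

    @property
    def n_states(self) -> int:
        return 4

    def to_generator(self) -> np.ndarray:
        a1, a2, b1, b2, g1, g2, d1, d2 = self.rates()
        Q = np.array(
            [
                [0.0, b1, a1, 0.0],  # from 00
                [d1, 0.0, 0.0, a2],  # from 01
                [g1, 0.0, 0.0, b2],  # from 10
                [0.0, g2, d2, 0.0],  # from 11
            ]
        )
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def _p2_batch(q01: float, q10: float, t: np.ndarray) -> np.ndarray:
    """Closed-form 2-state transition matrices for a vector of times, shape (E,2,2)."""
    t = np.asarray(t, dtype=float)
    tot = q01 + q10
    E = t.shape[0]
    P = np.empty((E, 2, 2))
    if tot == 0:
        P[:] = np.eye(2)
        return P
    e = np.exp(-tot * t)
    p1 = q01 / tot  # stationary prob of state 1
    P[:, 0, 1] = p1 * (1 - e)
    P[:, 0, 0] = 1 - P[:, 0, 1]
    P[:, 1, 0] = (1 - p1) * (1 - e)
    P[:, 1, 1] = 1 - P[:, 1, 0]
    return P


def _p4_batch(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q t) for a vector of times via eigendecomposition, shape (E,4,4).

    Falls back to scipy expm per branch when the eigenvector matrix is
    ill-conditioned (near-defective generator).
    """
    t = np.asarray(t, dtype=float)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.norm(V, 2) * np.linalg.norm(Vinv, 2)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e10:
        ew = np.exp(np.multiply.outer(t, w))  # (E, 4)
        P = np.einsum("ij,ej,jk->eik", V, ew, Vinv)
        P = np.ascontiguousarray(P.real)
    else:
        P = np.stack([expm(Q * ti) for ti in t])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def transition_probabilities(Q: RateMatrix2 | RateMatrix4, t: float) -> np.ndarray:
    """Transition-probability matrix ``P = exp(Qt)`` for branch length ``t >= 0``."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    tarr = np.array([float(t)])
    if isinstance(Q, RateMatrix2):
        return _p2_batch(Q.q01, Q.q10, tarr)[0]
    return _p4_batch(Q.to_generator(), tarr)[0]


def stationary_distribution(Q: np.ndarray) -> tuple[np.ndarray, bool]:
    """Stationary distribution of a CTMC generator.

    Solves ``pi Q = 0`` with ``sum(pi) = 1`` by least squares.  Returns
    ``(pi, reducible)`` where ``reducible`` flags a chain whose positive-rate
    graph is not a single communicating class; in that case the returned
    vector is the stationary distribution of the restricted (recurrent)
    chain, averaging closed classes uniformly if there are several.
    """
    n = Q.shape[0]
    # communicating structure on the positive-rate graph
    adj = Q > 1e-300
    np.fill_diagonal(adj, False)
    reach = _transitive_closure(adj)
    comm = reach & reach.T
    np.fill_diagonal(comm, True)
    classes: list[np.ndarray] = []
    seen = np.zeros(n, dtype=bool)
    for i in range(n):
        if not seen[i]:
            members = np.flatnonzero(comm[i])
            seen[members] = True
            classes.append(members)
    closed = [c for c in classes if not (reach[c][:, ~_mask(n, c)].any())]
    reducible = len(classes) > 1
    if len(closed) == 1 and closed[0].size == n:
        pi = _solve_stationary(Q)
        return pi, reducible
    # restricted chain(s)
    pi = np.zeros(n)
    for c in closed:
        if c.size == 1:
            pi_c = np.array([1.0])
        else:
            pi_c = _solve_stationary(Q[np.ix_(c, c)])
        pi[c] += pi_c / len(closed)
    return pi, True


def _mask(n: int, idx: np.ndarray) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[idx] = True
    return m


def _transitive_closure(adj: np.ndarray) -> np.ndarray:
    reach = adj.copy()
    n = adj.shape[0]
    for _ in range(n):
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    return reach


def _solve_stationary(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    return pi / s if s > 0 else np.full(n, 1.0 / n)


# ------------------------------------------------------------------- pruning


class PruningEngine:
    """Reusable pruning-likelihood evaluator for one tree and one state count.

    Precomputes a level schedule over the tree (all nodes in a level have
    fully-processed children) so that each likelihood evaluation is a small
    number of vectorised operations, which matters when the same tree is
    refitted tens of thousands of times.
    """

    def __init__(self, tree: Phylogeny, n_states: int, use_kernel: bool = True) -> None:
        self.tree = tree
        self.n_states = n_states
        n = tree.n_nodes
        level = np.zeros(n, dtype=np.int64)
        for v in tree.postorder:
            if tree.children[v]:
                level[v] = 1 + max(level[c] for c in tree.children[v])
        self.levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        max_level = int(level.max())
        for lv in range(1, max_level + 1):
            parents = np.array(
                [v for v in range(n) if level[v] == lv and tree.children[v]], dtype=np.int64
            )
            edge_child = np.concatenate([np.array(tree.children[v]) for v in parents])
            counts = np.array([len(tree.children[v]) for v in parents])
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            self.levels.append((parents, edge_child, starts))
        # edges indexed by child node id; edge_lengths[v] is branch above v
        self.edge_lengths = tree.edge_length
        self.root = tree.root
        # flat child arrays for the compiled kernel
        self.use_kernel = use_kernel and _kernels.HAVE_NUMBA
        child_off = np.zeros(n + 1, dtype=np.int64)
        for v in range(n):
            child_off[v + 1] = child_off[v] + len(tree.children[v])
        self.child_off = child_off
        self.child_flat = np.concatenate(
            [np.array(c, dtype=np.int64) for c in tree.children if c]
        ) if child_off[-1] else np.empty(0, dtype=np.int64)
        self.postorder = tree.postorder

    def transition_matrices(self, Q: RateMatrix2 | RateMatrix4) -> np.ndarray:
        """(n_nodes, S, S) array of P(edge above node); identity for the root."""
        if isinstance(Q, RateMatrix2):
            return _p2_batch(Q.q01, Q.q10, self.edge_lengths)
        return _p4_batch(Q.to_generator(), self.edge_lengths)

    def loglik(self, tip_partials: np.ndarray, Q: RateMatrix2 | RateMatrix4,
               root_prior: np.ndarray) -> float:
        """Log-likelihood given per-node tip partials (n_nodes, S; rows for
        internal nodes are ignored) under generator ``Q`` and a root prior."""
        if self.use_kernel:
            ll = _kernels._loglik_eig(
                Q.to_generator(),
                self.edge_lengths,
                self.postorder,
                self.child_flat,
                self.child_off,
                tip_partials,
                self.root,
                root_prior,
            )
            if not np.isnan(ll):
                return float(ll)
            # near-defective generator: fall through to the expm-based path
        P = self.transition_matrices(Q)
        L = tip_partials.astype(float, copy=True)
        log_scale = 0.0
        for parents, edge_child, starts in self.levels:
            M = np.einsum("eij,ej->ei", P[edge_child], L[edge_child])
            prod = np.multiply.reduceat(M, starts, axis=0)
            mx = prod.max(axis=1)
            if not (mx > 0).all():
                # a subtree has likelihood 0 in every state
                return LOG_ZERO
            prod = prod / mx[:, None]
            log_scale += float(np.log(mx).sum())
            L[parents] = prod
        lik = float(root_prior @ L[self.root])
        if lik <= 0 or not np.isfinite(log_scale):
            return LOG_ZERO
        return float(np.log(lik) + log_scale)


def tip_partials_for(tree: Phylogeny, states: np.ndarray | dict, n_states: int) -> np.ndarray:
    """One-hot partial-likelihood rows for tips, ordered by node id.

    ``states`` maps strain label -> state index, or is an array aligned with
    ``tree.tip_labels``.
    """
    if isinstance(states, dict):
        try:
            arr = np.array([states[lab] for lab in tree.tip_labels], dtype=np.int64)
        except KeyError as exc:
            raise PhylolinkError(f"tip {exc.args[0]!r} has no observed state") from exc
    else:
        arr = np.asarray(states, dtype=np.int64)
        if arr.shape[0] != tree.n_tips:
            raise PhylolinkError(
                f"expected {tree.n_tips} tip states, got {arr.shape[0]}"
            )
    if arr.min() < 0 or arr.max() >= n_states:
        raise PhylolinkError(f"tip states must be in [0, {n_states})")
    partials = np.ones((tree.n_nodes, n_states))
    for tip_node, s in zip(tree.tips, arr):
        partials[tip_node] = 0.0
        partials[tip_node, s] = 1.0
    return partials


def pair_states(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Encode two binary tip-state vectors as 4-state indices 2*a + b."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    return 2 * a + b


def tree_log_likelihood(
    tree: Phylogeny,
    tip_states: np.ndarray | dict,
    Q: RateMatrix2 | RateMatrix4,
    root_prior: str | np.ndarray = "uniform",
) -> float:
    """Felsenstein pruning log-likelihood of tip states under generator ``Q``.

    ``root_prior`` may be "uniform" (default), "stationary", or an explicit
    probability vector over states.
    """
    n_states = Q.n_states
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            prior = np.full(n_states, 1.0 / n_states)
        elif root_prior == "stationary":
            if isinstance(Q, RateMatrix2):
                prior = Q.stationary()
            else:
                prior, _ = stationary_distribution(Q.to_generator())
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
    else:
        prior = np.asarray(root_prior, dtype=float)
        if prior.shape != (n_states,) or abs(prior.sum() - 1.0) > 1e-8 or (prior < 0).any():
            raise ValueError("root prior must be a probability vector over states")
    engine = PruningEngine(tree, n_states)
    partials = tip_partials_for(tree, tip_states, n_states)
    return engine.loglik(partials, Q, prior)
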