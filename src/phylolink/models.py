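"""Maximum-likelihood models for binary-trait evolution on a phylogeny.

The public surface follows the Model/Results convention: a model object is
built from data (tree + tip states), ``fit()`` returns a results object
carrying estimates, log-likelihood, convergence diagnostics and a
``summary()`` table.

Two models are provided.  ``BinaryTraitModel`` fits a 2-state chain (gain
rate q01, loss rate q10) to one trait.  ``PairedTraitModel`` fits a trait
pair either under independent evolution (4 free rates; the likelihood
factorises into two single-trait problems) or under dependent evolution
(8 free rates, each trait's gain/loss depending on the partner's state).
The likelihood-ratio statistic between the two, referred to chi-square with
4 degrees of freedom, is the correlated-evolution test; the direction
statistic RQ is the stationary probability mass on the concordant states
(0,0) and (1,1) of the fitted dependent chain.

Trees are rescaled internally so that the mean root-to-tip depth is 1;
rates are reported in these scaled units (rate ratios are scale-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .ctmc import (
    LOG_ZERO,
    PruningEngine,
    RateMatrix2,
    RateMatrix4,
    stationary_distribution,
    tip_partials_for,
    pair_states,
)
from .io import Phylogeny, PhylolinkError, TraitMatrix

__all__ = [
    "BinaryTraitModel",
    "BinaryTraitResults",
    "PairedTraitModel",
    "PairedTraitResults",
    "fit_model",
    "rq_statistic",
    "lrt_pair",
    "gain_loss_summary",
    "GainLossSummary",
]

RATE_LO = 1e-6
RATE_HI = 1e3
#: starting points are drawn log-uniformly from this narrower box
START_LO, START_HI = 1e-3, 1e2


def _prepare_tree(tree: Phylogeny, rescale: bool) -> tuple[Phylogeny, float]:
    if not rescale:
        return tree, 1.0
    depth = tree.mean_tip_depth()
    if depth <= 0:
        return tree, 1.0
    return tree.rescaled(1.0 / depth), 1.0 / depth


def _root_prior(spec, n_states: int, Q=None) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "uniform":
            return np.full(n_states, 1.0 / n_states)
        raise ValueError(f"unknown root prior {spec!r}")
    return np.asarray(spec, dtype=float)


def _optimize(fun, x0_list, bounds, ftol=1e-11):
    """Minimise over several starts; return (best_x, best_f, n_ok, all_ok)."""
    best_x, best_f, best_norm = None, np.inf, np.inf
    n_ok = 0
    for x0 in x0_list:
        res = minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-8, "maxiter": 500},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            norm = float(np.linalg.norm(res.x))
            # tie between restarts: highest lnL, then lowest parameter norm
            if res.fun < best_f - 1e-9 or (abs(res.fun - best_f) <= 1e-9 and norm < best_norm):
                best_x, best_f, best_norm = res.x, float(res.fun), norm
    return best_x, best_f, n_ok


def _near_bound(rate: float) -> bool:
    return rate <= RATE_LO * 1.5 or rate >= RATE_HI / 1.5


# ----------------------------------------------------------------- single trait


class BinaryTraitModel:
    """ML model for one binary trait evolving by a 2-state chain on a tree.

    Parameters
    ----------
    tree : Phylogeny
        Rooted tree whose tips carry the observations.
    states : array-like or dict
        Binary state per tip, ordered as ``tree.tip_labels`` (or a mapping
        from strain id to state).
    root_prior : str or array
        "uniform" (default) or an explicit length-2 probability vector.
    rescale : bool
        Rescale the tree to mean root-to-tip depth 1 before fitting.
    """

    def __init__(self, tree: Phylogeny, states, *, root_prior="uniform", rescale=True,
                 engine: PruningEngine | None = None):
        self.original_tree = tree
        if engine is not None:
            self.tree = engine.tree
            self.scale_factor = None
            self.engine = engine
        else:
            self.tree, self.scale_factor = _prepare_tree(tree, rescale)
            self.engine = PruningEngine(self.tree, 2)
        self.partials = tip_partials_for(self.tree, states, 2)
        self.states = np.asarray(
            [states[lab] for lab in tree.tip_labels] if isinstance(states, dict) else states,
            dtype=np.int64,
        )
        self.prior = _root_prior(root_prior, 2)

    def loglike(self, q01: float, q10: float) -> float:
        return self.engine.loglik(self.partials, RateMatrix2(q01, q10), self.prior)

    def fit(self, seed: int = 0, n_restarts: int = 5) -> "BinaryTraitResults":
        rng = np.random.default_rng(seed)
        bounds = [(np.log(RATE_LO), np.log(RATE_HI))] * 2

        def nll(x):
            ll = self.loglike(*np.exp(x))
            return -ll if ll > LOG_ZERO else 1e12

        starts = [np.log([1.0, 1.0])]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(rng.uniform(np.log(START_LO), np.log(START_HI), size=2))
        x, f, n_ok = _optimize(nll, starts, bounds)
        converged = n_ok > 0 and f < 1e11
        q01, q10 = (np.exp(x) if x is not None else (np.nan, np.nan))
        degenerate = (not converged) or _near_bound(q01) or _near_bound(q10)
        return BinaryTraitResults(
            model=self,
            q01=float(q01),
            q10=float(q10),
            llf=-f if converged else -np.inf,
            converged=converged,
            restarts=len(starts),
            seed=seed,
            degenerate=degenerate,
        )


@dataclass
class BinaryTraitResults:
    """Fitted 2-state gain/loss model for one binary trait."""

    model: BinaryTraitModel
    q01: float
    q10: float
    llf: float
    converged: bool
    restarts: int
    seed: int
    degenerate: bool
    model_kind: str = "single"

    @property
    def rates(self) -> dict[str, float]:
        return {"q01": self.q01, "q10": self.q10}

    @property
    def gain_loss_ratio(self) -> float:
        return self.q01 / self.q10

    def to_json_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "rates": self.rates,
            "lnl": self.llf,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "restarts": self.restarts,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            "Binary trait evolution (2-state CTMC)",
            "=" * 46,
            f"Tips:               {self.model.tree.n_tips}",
            f"Log-likelihood:     {self.llf:.6f}",
            f"Converged:          {self.converged}  (restarts: {self.restarts})",
            f"Degenerate:         {self.degenerate}",
            f"gain rate q01:      {self.q01:.6g}",
            f"loss rate q10:      {self.q10:.6g}",
            f"gain/loss ratio:    {self.gain_loss_ratio:.6g}",
            "(rates per unit of the depth-rescaled tree)",
        ]
        return "\n".join(lines)


# ------------------------------------------------------------------ trait pair


class PairedTraitModel:
    """ML model for a pair of binary traits on a tree (independent or dependent).

    The pair state space is {(0,0), (0,1), (1,0), (1,1)}; dual-change rates
    are fixed at 0.  ``fit(kind="independent")`` constrains each trait's
    rates to ignore the partner (4 free parameters, fitted by factorising
    into two single-trait problems); ``fit(kind="dependent")`` frees all 8.
    """

    def __init__(self, tree: Phylogeny, states_a, states_b, *, root_prior="uniform",
                 rescale=True, engine: PruningEngine | None = None):
        self.original_tree = tree
        if engine is not None:
            self.tree = engine.tree
            self.scale_factor = None
            self.engine = engine
        else:
            self.tree, self.scale_factor = _prepare_tree(tree, rescale)
            self.engine = PruningEngine(self.tree, 4)
        a = np.asarray(
            [states_a[lab] for lab in tree.tip_labels] if isinstance(states_a, dict) else states_a,
            dtype=np.int64,
        )
        b = np.asarray(
            [states_b[lab] for lab in tree.tip_labels] if isinstance(states_b, dict) else states_b,
            dtype=np.int64,
        )
        self.states_a, self.states_b = a, b
        self.partials = tip_partials_for(self.tree, pair_states(a, b), 4)
        self.prior = _root_prior(root_prior, 4)

    def loglike(self, rates) -> float:
        return self.engine.loglik(self.partials, RateMatrix4(*rates), self.prior)

    # -- fitting -----------------------------------------------------------
    def fit(self, kind: str = "dependent", seed: int = 0, n_restarts: int = 5):
        if kind == "independent":
            return self._fit_independent(seed, n_restarts)
        if kind == "dependent":
            return self._fit_dependent(seed, n_restarts)
        raise ValueError(f"kind must be 'independent' or 'dependent', got {kind!r}")

    def _single_models(self) -> tuple[BinaryTraitModel, BinaryTraitModel]:
        ma = BinaryTraitModel(self.tree, self.states_a, rescale=False)
        mb = BinaryTraitModel(self.tree, self.states_b, rescale=False)
        return ma, mb

    def _fit_independent(self, seed: int, n_restarts: int) -> "PairedTraitResults":
        ma, mb = self._single_models()
        ra = ma.fit(seed=seed, n_restarts=n_restarts)
        rb = mb.fit(seed=seed + 1, n_restarts=n_restarts)
        converged = ra.converged and rb.converged
        rates = RateMatrix4.independent(
            RateMatrix2(ra.q01, ra.q10), RateMatrix2(rb.q01, rb.q10)
        )
        llf = self.loglike(rates.rates()) if converged else -np.inf
        return PairedTraitResults(
            model=self,
            kind="pair-independent",
            rate_matrix=rates,
            llf=llf,
            converged=converged,
            restarts=ra.restarts + rb.restarts,
            seed=seed,
            degenerate=ra.degenerate or rb.degenerate,
        )

    def _fit_dependent(self, seed: int, n_restarts: int,
                       indep: "PairedTraitResults | None" = None) -> "PairedTraitResults":
        if indep is None:
            indep = self._fit_independent(seed, max(2, n_restarts - 2))
        rng = np.random.default_rng(seed)
        bounds = [(np.log(RATE_LO), np.log(RATE_HI))] * 8

        def nll(x):
            ll = self.loglike(np.exp(x))
            return -ll if ll > LOG_ZERO else 1e12

        starts = []
        if indep.converged:
            x_ind = np.log(np.clip(indep.rate_matrix.rates(), RATE_LO, RATE_HI))
            starts.append(x_ind)
            # nudge toward positive coupling as a second deterministic start
            nudge = np.log(np.array([0.5, 2.0, 0.5, 2.0, 2.0, 0.5, 2.0, 0.5]))
            starts.append(np.clip(x_ind + nudge, np.log(RATE_LO), np.log(RATE_HI)))
        while len(starts) < max(1, n_restarts):
            starts.append(rng.uniform(np.log(START_LO), np.log(START_HI), size=8))
        x, f, n_ok = _optimize(nll, starts, bounds)
        converged = n_ok > 0 and f < 1e11
        rates = RateMatrix4(*np.exp(x)) if x is not None else None
        degenerate = (not converged) or any(_near_bound(r) for r in (rates.rates() if rates else []))
        res = PairedTraitResults(
            model=self,
            kind="pair-dependent",
            rate_matrix=rates,
            llf=-f if converged else -np.inf,
            converged=converged,
            restarts=len(starts),
            seed=seed,
            degenerate=degenerate,
        )
        # guard the nesting property against optimiser noise: the dependent
        # model contains the independent one, so its lnL may not be lower
        if indep.converged and converged and res.llf < indep.llf:
            res.llf = max(res.llf, self.loglike(indep.rate_matrix.rates()))
            if res.llf < indep.llf:
                res.llf = indep.llf
                res.rate_matrix = indep.rate_matrix
        return res

    def fit_both(self, seed: int = 0, n_restarts: int = 5
                 ) -> tuple["PairedTraitResults", "PairedTraitResults"]:
        """Fit the independent and dependent models, sharing the independent
        optimum as a dependent starting point (the cheap, standard path)."""
        indep = self._fit_independent(seed, n_restarts)
        dep = self._fit_dependent(seed, n_restarts, indep=indep)
        return indep, dep


@dataclass
class PairedTraitResults:
    """Fitted pair model (independent or dependent rates)."""

    model: PairedTraitModel
    kind: str
    rate_matrix: RateMatrix4 | None
    llf: float
    converged: bool
    restarts: int
    seed: int
    degenerate: bool
    _rq: float | None = field(default=None, repr=False)
    rq_reducible: bool = False

    @property
    def rates(self) -> dict[str, float]:
        if self.rate_matrix is None:
            return {}
        names = ["alpha1", "alpha2", "beta1", "beta2", "gamma1", "gamma2", "delta1", "delta2"]
        return dict(zip(names, self.rate_matrix.rates()))

    @property
    def rq(self) -> float:
        if self._rq is None:
            self._rq = rq_statistic(self)
        return self._rq

    def to_json_dict(self) -> dict:
        return {
            "model_kind": self.kind,
            "rates": self.rates,
            "lnl": self.llf,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "restarts": self.restarts,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            f"Trait-pair evolution ({self.kind})",
            "=" * 46,
            f"Tips:               {self.model.tree.n_tips}",
            f"Log-likelihood:     {self.llf:.6f}",
            f"Converged:          {self.converged}  (restarts: {self.restarts})",
            f"Degenerate:         {self.degenerate}",
        ]
        for k, v in self.rates.items():
            lines.append(f"{k:<8} {v:.6g}")
        if self.kind == "pair-dependent" and self.converged:
            lines.append(f"RQ (stationary concordance): {self.rq:.4f}")
        return "\n".join(lines)


# ------------------------------------------------------------------ statistics


def rq_statistic(dep: PairedTraitResults) -> float:
    """Direction statistic RQ of a fitted dependent pair model.

    RQ is the stationary probability of the concordant states (0,0) and
    (1,1) under the fitted 4-state generator: > 0.5 indicates positive
    association (traits co-occur at equilibrium), < 0.5 anti-association.
    For a reducible generator the statistic is computed on the restricted
    recurrent chain and ``dep.rq_reducible`` is set.
    """
    if not dep.converged or dep.rate_matrix is None:
        raise PhylolinkError("RQ requires a converged dependent fit")
    pi, reducible = stationary_distribution(dep.rate_matrix.to_generator())
    dep.rq_reducible = bool(reducible)
    return float(pi[0] + pi[3])


def lrt_pair(indep: PairedTraitResults, dep: PairedTraitResults) -> tuple[float, float]:
    """Likelihood-ratio test of dependent vs independent evolution.

    Returns ``(D, p)`` with ``D = 2 (lnL_dep − lnL_indep)`` clipped at 0 and
    ``p`` the upper tail of chi-square with 4 degrees of freedom (8 − 4
    parameters).
    """
    if not (indep.converged and dep.converged):
        raise PhylolinkError("LRT requires two converged fits")
    D = max(0.0, 2.0 * (dep.llf - indep.llf))
    return D, float(chi2.sf(D, df=4))


def fit_model(tree: Phylogeny, traits, kind: str, seed: int = 0, n_restarts: int = 5):
    """Functional wrapper over the model classes.

    ``kind`` is "single" (traits = one binary vector), "pair-independent" or
    "pair-dependent" (traits = tuple of two binary vectors).
    """
    if kind == "single":
        return BinaryTraitModel(tree, traits).fit(seed=seed, n_restarts=n_restarts)
    if kind in ("pair-independent", "pair-dependent"):
        a, b = traits
        model = PairedTraitModel(tree, a, b)
        which = "independent" if kind == "pair-independent" else "dependent"
        return model.fit(kind=which, seed=seed, n_restarts=n_restarts)
    raise ValueError(f"unknown model kind {kind!r}")


# --------------------------------------------------------------- rate summary


@dataclass
class GainLossSummary:
    """Distribution of per-trait gain/loss rate ratios across a trait matrix."""

    ratios: dict[str, float]
    median_ratio: float
    mad_ratio: float
    n_traits: int
    n_converged: int
    n_excluded: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Gain/loss rate ratios (per-trait 2-state ML fits)",
                "=" * 50,
                f"Traits fitted:        {self.n_traits}",
                f"Converged, informative: {self.n_converged}",
                f"Excluded (degenerate): {self.n_excluded}",
                f"median(q01/q10):      {self.median_ratio:.4g}",
                f"MAD(q01/q10):         {self.mad_ratio:.4g}",
            ]
        )


def gain_loss_summary(matrix: TraitMatrix, tree: Phylogeny, seed: int = 0,
                      n_restarts: int = 3) -> GainLossSummary:
    """Fit every trait's gain and loss rate and summarise the q01/q10 ratios.

    Only converged, non-degenerate fits (no rate at a bound, trait showing
    both states) enter the median and MAD.
    """
    strains = tree.tip_labels
    data = matrix.reindex_strains(strains).data
    scaled, _ = _prepare_tree(tree, True)
    engine2 = PruningEngine(scaled, 2)
    ratios: dict[str, float] = {}
    n_fit = n_excl = 0
    ss = np.random.SeedSequence(seed)
    for j, trait in enumerate(data.columns):
        states = data.iloc[:, j].to_numpy()
        if states.min() == states.max():
            n_excl += 1
            continue
        model = BinaryTraitModel(scaled, states, engine=engine2)
        res = model.fit(seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
                        n_restarts=n_restarts)
        n_fit += 1
        if res.converged and not res.degenerate:
            ratios[trait] = res.gain_loss_ratio
        else:
            n_excl += 1
    if not ratios:
        raise PhylolinkError("no informative traits: all fits degenerate or constant")
    vals = np.array(list(ratios.values()))
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return GainLossSummary(
        ratios=ratios,
        median_ratio=med,
        mad_ratio=mad,
        n_traits=n_fit,
        n_excluded=n_excl,
        n_converged=len(ratios),
    )
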