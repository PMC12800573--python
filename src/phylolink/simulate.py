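"""Synthetic data with known ground truth: trees, traits, linked pairs, fixtures.

The generator emulates the statistical structure the association analysis
assumes: a few dozen strains on a Yule tree rescaled to unit depth; sparse
binary traits evolving with a very low gain/loss rate ratio (default median
0.016, so that at stationarity a trait is carried by under 2% of lineages);
a configurable number of truly linked GCF–MF pairs evolving under a
dependent-rates chain with a single coupling factor kappa (gain-with-partner
rates multiplied by kappa, loss-with-partner rates divided by kappa); and a
metabolite false-negative (dropout) rate emulating condition-dependent
non-production.  Toy gene tables with plantable superclusters and toy
feature tables with adduct labels feed the curation and MF-calling stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import RateMatrix2, RateMatrix4
from .io import Phylogeny, PhylolinkError, TraitMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_trait",
    "synthesize_dataset",
    "synthesize_curation_fixture",
    "synthesize_feature_table",
]


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic dataset.

    72 strains, 265 GCF traits and 99 MF traits match the scale of the
    dataset the analysis is designed for; the gain/loss ratio default of
    0.016 is the low median observed for gene-cluster traits.  ``kappa`` is
    the coupling effect size for truly linked pairs; ``mf_dropout`` is the
    probability that a truly produced metabolite goes undetected in a strain.
    """

    n_strains: int = 72
    tree_model: str = "yule"
    birth_rate: float = 1.0
    n_gcf_traits: int = 265
    n_mf_traits: int = 99
    gain_loss_ratio: float = 0.016
    ratio_sigma: float = 0.4  # lognormal spread of per-trait ratios
    loss_rate: float = 1.0  # median per-trait loss rate on the unit-depth tree
    loss_sigma: float = 0.5
    n_linked_pairs: int = 0
    kappa: float = 16.0
    linked_loss_rate: float = 4.0  # median loss rate of truly linked pairs
    mf_dropout: float = 0.1
    min_events: int = 2  # parsimony changes required of every linked trait
    max_retries: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not (0 <= self.mf_dropout < 1):
            raise ValueError("mf_dropout must be in [0, 1)")
        if self.gain_loss_ratio <= 0 or self.loss_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.n_linked_pairs > min(self.n_gcf_traits, self.n_mf_traits):
            raise ValueError("more linked pairs than traits")


@dataclass
class SyntheticTruth:
    """A synthetic dataset plus everything a test needs to score a method."""

    tree: Phylogeny
    gcf: TraitMatrix
    mf: TraitMatrix
    linked_pairs: pd.DataFrame  # pair_id, gcf_id, mf_id, kappa
    trait_rates: pd.DataFrame  # trait_id, kind, q01, q10
    config: SimulationConfig
    retry_log: list[str] = field(default_factory=list)


def simulate_tree(n: int, model: str = "yule", seed: int = 0, birth_rate: float = 1.0
                  ) -> Phylogeny:
    """Simulate a Yule (pure-birth) tree with ``n`` tips, rescaled to mean
    root-to-tip depth 1.  Tip labels are ``S01, S02, ...`` in tip order."""
    if n < 2:
        raise PhylolinkError("need at least 2 tips")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)
    # grow: start with 2 lineages from the root; at each step every extant
    # lineage waits Exp(k * birth_rate), one uniformly chosen lineage splits
    parent = [-1, 0, 0]
    birth_time = [0.0, None, None]  # split time of internal nodes
    active = [1, 2]  # current leaves
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        birth_time[node] = t
        parent.extend([node, node])
        birth_time.extend([None, None])
        active.extend([len(parent) - 2, len(parent) - 1])
    t_end = t + rng.exponential(1.0 / (len(active) * birth_rate))
    # edge lengths from split times; leaves extend to t_end (ultrametric)
    n_nodes = len(parent)
    lengths = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    width = len(str(n))
    leaf_counter = 0
    for v in range(1, n_nodes):
        end = birth_time[v] if birth_time[v] is not None else t_end
        lengths[v] = end - birth_time[parent[v]]
    for v in range(n_nodes):
        if birth_time[v] is None and v != 0:
            leaf_counter += 1
            labels[v] = f"S{leaf_counter:0{width}d}"
    tree = Phylogeny(np.array(parent), lengths, labels)
    depth = tree.mean_tip_depth()
    return tree.rescaled(1.0 / depth)


def _sim_chain(rng: np.random.Generator, G: np.ndarray, state: int, t: float) -> int:
    """Exact CTMC simulation along one edge (competing exponential waits)."""
    while True:
        out = -G[state, state]
        if out <= 0:
            return state
        wait = rng.exponential(1.0 / out)
        if wait > t:
            return state
        t -= wait
        probs = G[state].clip(0)
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(len(probs), p=probs))


def simulate_trait(tree: Phylogeny, Q: RateMatrix2 | RateMatrix4,
                   root_prior: str | np.ndarray = "stationary",
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Forward-simulate one trait (or trait pair) on the tree.

    Returns tip states ordered as ``tree.tip_labels``: a binary vector for a
    2-state generator, or an (n_tips, 2) array of the two binary traits for
    a 4-state pair generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = Q.to_generator()
    n_states = G.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            if isinstance(Q, RateMatrix2):
                prior = Q.stationary()
            else:
                from .ctmc import stationary_distribution

                prior, _ = stationary_distribution(G)
        elif root_prior == "uniform":
            prior = np.full(n_states, 1.0 / n_states)
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
    else:
        prior = np.asarray(root_prior, dtype=float)
    state = np.empty(tree.n_nodes, dtype=np.int64)
    state[tree.root] = rng.choice(n_states, p=prior)
    for v in tree.postorder[::-1]:  # preorder
        p = tree.parent[v]
        if p >= 0:
            state[v] = _sim_chain(rng, G, int(state[p]), float(tree.edge_length[v]))
    tips = state[tree.tips]
    if n_states == 2:
        return tips
    return np.stack([tips // 2, tips % 2], axis=1)  # A = high bit, B = low bit


def _coupled_rates(q01a: float, q10a: float, q01b: float, q10b: float, kappa: float
                   ) -> RateMatrix4:
    """Dependent pair generator: partner presence boosts gain, slows loss."""
    return RateMatrix4(
        alpha1=q01a, alpha2=q01a * kappa,
        beta1=q01b, beta2=q01b * kappa,
        gamma1=q10a, gamma2=q10a / kappa,
        delta1=q10b, delta2=q10b / kappa,
    )


def synthesize_dataset(config: SimulationConfig) -> SyntheticTruth:
    """Generate a full synthetic dataset with ground truth.

    Truly linked pairs are resimulated (bounded retries) until both members
    show at least ``config.min_events`` parsimony changes on the tree, so
    every truth pair passes the eligibility filter by construction.  MF
    dropout is applied after simulation (and before the event check, so the
    check holds for the observed matrix).
    """
    from .association import parsimony_changes

    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits = ss.spawn(2)
    tree = simulate_tree(config.n_strains, config.tree_model,
                         seed=int(s_tree.generate_state(1)[0] % (2**31)),
                         birth_rate=config.birth_rate)
    rng = np.random.default_rng(s_traits)
    strains = tree.tip_labels
    retry_log: list[str] = []

    def draw_rates(loss_median: float | None = None) -> tuple[float, float]:
        ratio = config.gain_loss_ratio * float(
            np.exp(rng.normal(0.0, config.ratio_sigma))
        )
        q10 = (loss_median if loss_median is not None else config.loss_rate) * float(
            np.exp(rng.normal(0.0, config.loss_sigma))
        )
        return ratio * q10, q10

    gcf_cols: dict[str, np.ndarray] = {}
    mf_cols: dict[str, np.ndarray] = {}
    rate_rows = []
    gcf_ids = [f"GCF{j + 1:04d}" for j in range(config.n_gcf_traits)]
    mf_ids = [f"MF{j + 1:03d}" for j in range(config.n_mf_traits)]
    linked = []

    def apply_dropout(states: np.ndarray) -> np.ndarray:
        if config.mf_dropout == 0:
            return states
        drop = rng.random(states.shape[0]) < config.mf_dropout
        return np.where(drop, 0, states)

    # linked pairs occupy the first columns of each matrix; the observed
    # linked pairs are those whose histories produced enough events to be
    # observable, so base rates are redrawn on every rejection
    for k in range(config.n_linked_pairs):
        ok = False
        for attempt in range(config.max_retries):
            q01a, q10a = draw_rates(config.linked_loss_rate)
            q01b, q10b = draw_rates(config.linked_loss_rate)
            Q = _coupled_rates(q01a, q10a, q01b, q10b, config.kappa)
            ab = simulate_trait(tree, Q, seed=rng)
            a, b = ab[:, 0].copy(), apply_dropout(ab[:, 1].copy())
            if (
                parsimony_changes(tree, a) >= config.min_events
                and parsimony_changes(tree, b) >= config.min_events
            ):
                ok = True
                break
        if not ok:
            raise PhylolinkError(
                f"linked pair {k}: retry budget exhausted; "
                "increase kappa or the trait rates"
            )
        if attempt > 0:
            retry_log.append(f"linked pair {k}: {attempt + 1} attempts")
        gcf_cols[gcf_ids[k]] = a
        mf_cols[mf_ids[k]] = b
        rate_rows.append((gcf_ids[k], "GCF", Q.alpha1, Q.gamma1))
        rate_rows.append((mf_ids[k], "MF", Q.beta1, Q.delta1))
        linked.append((f"pair{k + 1:02d}", gcf_ids[k], mf_ids[k], config.kappa))

    def fill_independent(ids: list[str], cols: dict, kind: str, dropout: bool) -> None:
        # only observed (non-empty) traits enter real incidence matrices
        for tid in ids:
            if tid in cols:
                continue
            for _ in range(config.max_retries):
                q01, q10 = draw_rates()
                states = simulate_trait(tree, RateMatrix2(q01, q10), seed=rng)
                if dropout:
                    states = apply_dropout(states)
                if states.any():
                    break
            cols[tid] = states
            rate_rows.append((tid, kind, q01, q10))

    fill_independent(gcf_ids, gcf_cols, "GCF", dropout=False)
    fill_independent(mf_ids, mf_cols, "MF", dropout=True)

    gcf = TraitMatrix(pd.DataFrame(gcf_cols, index=strains)[gcf_ids], "GCF")
    mf = TraitMatrix(pd.DataFrame(mf_cols, index=strains)[mf_ids], "MF")
    truth = pd.DataFrame(linked, columns=["pair_id", "gcf_id", "mf_id", "kappa"])
    rates = pd.DataFrame(rate_rows, columns=["trait_id", "kind", "q01", "q10"])
    return SyntheticTruth(
        tree=tree, gcf=gcf, mf=mf, linked_pairs=truth, trait_rates=rates,
        config=config, retry_log=retry_log,
    )


# ------------------------------------------------------------ curation fixture


def synthesize_curation_fixture(
    seed: int = 0,
    n_superclusters: int = 1,
    n_distractors: int = 2,
    blocks_per_supercluster: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene tables with planted superclusters, plus the expected split log.

    Each planted supercluster fuses 2–3 core blocks (with distinct domain
    families) into one region of genome ``GEN_Ak``; partner genomes carry the
    single blocks as standalone regions, providing the cross-strain evidence
    the splitter requires.  Distractor regions have unique domain content and
    must never be split.

    Returns ``(gene_table, expected_splits)``; the gene table has the
    columns genome_id, contig_id, region_id, gene_id, start, end, strand,
    category, domains.
    """
    rng = np.random.default_rng(seed)
    rows = []
    expected = []

    def add_gene(genome, contig, region, idx, start, category, domains):
        length = int(rng.integers(900, 3000))
        rows.append(
            {
                "genome_id": genome,
                "contig_id": contig,
                "region_id": region,
                "gene_id": f"{region}_g{idx:02d}",
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "category": category,
                "domains": domains,
            }
        )
        return start + length + int(rng.integers(50, 400))

    def block_genes(tag: str, n_core: int = 2, n_extra: int = 1) -> list[tuple[str, str]]:
        genes = [("core", f"{tag}_KS|{tag}_AT")]
        for i in range(n_core - 1):
            genes.append(("core", f"{tag}_KS"))
        for i in range(n_extra):
            genes.append(("additional", f"{tag}_tail"))
        return genes

    for k in range(n_superclusters):
        tags = [f"FAM{k}{chr(ord('X') + b)}" for b in range(blocks_per_supercluster)]
        fused_genome = f"GEN_A{k}"
        fused_region = f"{fused_genome}_r1"
        pos = int(rng.integers(1, 5000))
        idx = 0
        for b, tag in enumerate(tags):
            for category, domains in block_genes(tag):
                idx += 1
                pos = add_gene(fused_genome, "c1", fused_region, idx, pos, category, domains)
            if b < len(tags) - 1:  # non-core spacer between blocks
                idx += 1
                pos = add_gene(fused_genome, "c1", fused_region, idx, pos, "other", "spacer")
        # partner genomes carrying exactly one block each
        children = []
        for b, tag in enumerate(tags):
            pg = f"GEN_B{k}{b}"
            region = f"{pg}_r1"
            pos2 = int(rng.integers(1, 5000))
            jdx = 0
            for category, domains in block_genes(tag):
                jdx += 1
                pos2 = add_gene(pg, "c1", region, jdx, pos2, category, domains)
            children.append(region)
        for b in range(blocks_per_supercluster):
            expected.append(
                {
                    "parent": fused_region,
                    "child_index": b,
                    "evidence": ",".join(children),
                }
            )
    for d in range(n_distractors):
        genome = f"GEN_D{d}"
        region = f"{genome}_r1"
        pos = int(rng.integers(1, 5000))
        for i in range(3):
            cat = "core" if i == 0 else "other"
            pos = add_gene(genome, "c1", region, i + 1, pos, cat, f"DIS{d}_dom{i}")
    gene_table = pd.DataFrame(rows)
    expected_df = pd.DataFrame(expected, columns=["parent", "child_index", "evidence"])
    return gene_table, expected_df


# ------------------------------------------------------------- feature fixture


def synthesize_feature_table(
    mf: TraitMatrix,
    seed: int = 0,
    features_per_mf: tuple[int, int] = (5, 40),
    detected_fraction: float = 0.3,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Toy LC-MS feature table consistent with a given MF presence matrix.

    For every (strain, MF) marked present, a random subset of the MF's
    features (at least 3% of them, always including one [M+H]+ feature) is
    marked detected in at least one replicate; absent combinations receive
    no detections.  Columns: feature_id, mf_id, adduct, strain_id,
    replicate_id, detected.
    """
    rng = np.random.default_rng(seed)
    adducts = ["[M+H]+", "[M+Na]+", "[M+K]+", "[M+H-H2O]+"]
    rows = []
    for mf_id in mf.traits:
        n_feat = int(rng.integers(*features_per_mf))
        feat_ids = [f"{mf_id}_f{i:03d}" for i in range(n_feat)]
        feat_adducts = ["[M+H]+"] + [
            adducts[int(rng.integers(len(adducts)))] for _ in range(n_feat - 1)
        ]
        present = mf.data[mf_id]
        for strain in mf.strains:
            if present[strain]:
                n_det = max(1, int(np.ceil(0.03 * n_feat)),
                            int(rng.binomial(n_feat, detected_fraction)))
                chosen = set(rng.choice(n_feat, size=min(n_det, n_feat), replace=False))
                chosen.add(0)  # guarantee the [M+H]+ feature
            else:
                chosen = set()
            for i, (fid, adduct) in enumerate(zip(feat_ids, feat_adducts)):
                if i in chosen:
                    rep = 1 + int(rng.integers(n_replicates))
                    for r in range(1, n_replicates + 1):
                        rows.append((fid, mf_id, adduct, strain, f"rep{r}",
                                     int(r == rep or rng.random() < 0.5)))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "mf_id", "adduct", "strain_id", "replicate_id", "detected"],
    )
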