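"""Comparative curation of biosynthetic gene cluster (BGC) regions.

Predicted BGC regions frequently have imprecise boundaries; in particular a
greedy predictor can emit "superclusters", overly long regions fusing
several independent clusters.  This module curates a set of regions by

1. splitting superclusters, using cross-strain evidence: if another genome
   in the same gene cluster family (GCF) carries a shorter region matching
   exactly one core-gene block of a long region, the blocks are considered
   individually functional and the long region is cut in the core-free gap
   between them;
2. reducing regions to their core biosynthetic genes, so that family
   clustering ignores accessory/transport/regulatory/"other" genes inside
   uncertain boundaries;
3. clustering regions into GCFs with a declared stand-in distance (weighted
   Jaccard on domain content plus domain-bigram adjacency), single-linkage
   at a cutoff.  This stand-in is NOT a re-implementation of the external
   BiG-SCAPE tool; it exists so the pipeline runs end-to-end on synthetic
   data, and is labelled as such in logs.

Coordinates are 1-based inclusive; strand never affects matching (domain
content and order only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import PhylolinkError, TraitMatrix, ValidationError

__all__ = [
    "Gene",
    "BGCRegion",
    "GCF",
    "MatchBlock",
    "read_gene_table",
    "regions_from_frame",
    "regions_to_frame",
    "match_blocks",
    "split_superclusters",
    "reduce_to_core",
    "reduce_all_to_core",
    "cluster_gcfs",
    "gcf_presence_matrix",
]

GENE_CATEGORIES = ("core", "additional", "transport", "regulatory", "other")


@dataclass(frozen=True)
class Gene:
    """One gene in a BGC region (1-based inclusive coordinates)."""

    gene_id: str
    start: int
    end: int
    strand: str
    category: str
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.category not in GENE_CATEGORIES:
            raise ValidationError(
                f"gene {self.gene_id}: category {self.category!r} not in {GENE_CATEGORIES}"
            )

    @property
    def is_core(self) -> bool:
        return self.category == "core"


@dataclass(frozen=True)
class BGCRegion:
    """An ordered run of genes on a genome interval, with a product-class tag."""

    region_id: str
    genome_id: str
    contig_id: str
    genes: tuple[Gene, ...]
    product_class: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"region {self.region_id}: no genes")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            object.__setattr__(self, "genes", tuple(sorted(self.genes, key=lambda g: g.start)))

    @property
    def interval(self) -> tuple[int, int]:
        return (self.genes[0].start, max(g.end for g in self.genes))

    @property
    def core_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.genes) if g.is_core]

    def domain_set(self) -> frozenset[str]:
        return frozenset(d for g in self.genes for d in g.domains)

    def domain_bigrams(self) -> frozenset[tuple[str, str]]:
        seq = [d for g in self.genes for d in g.domains]
        return frozenset(zip(seq, seq[1:]))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GCF:
    """A gene cluster family: ids of its member regions."""

    gcf_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"GCF {self.gcf_id}: no members")


@dataclass(frozen=True)
class MatchBlock:
    """A collinear run of genes shared between two regions.

    ``a_range``/``b_range`` are inclusive gene-index ranges on each region;
    ``anchor`` is the set of domain families shared between core genes of
    the two matched ranges (always non-empty).
    """

    region_a: str
    region_b: str
    a_range: tuple[int, int]
    b_range: tuple[int, int]
    anchor: frozenset[str]


# ----------------------------------------------------------------------- I/O

GENE_TABLE_COLUMNS = [
    "genome_id", "contig_id", "region_id", "gene_id",
    "start", "end", "strand", "category", "domains",
]


def regions_from_frame(df: pd.DataFrame) -> list[BGCRegion]:
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"gene table missing columns: {sorted(missing)}")
    regions = []
    for (genome, contig, rid), sub in df.groupby(
        ["genome_id", "contig_id", "region_id"], sort=True
    ):
        genes = tuple(
            Gene(
                gene_id=str(r.gene_id),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                category=str(r.category),
                domains=tuple(str(r.domains).split("|")) if str(r.domains) else (),
            )
            for r in sub.sort_values("start").itertuples()
        )
        pclass = str(sub["product_class"].iloc[0]) if "product_class" in sub else ""
        regions.append(BGCRegion(str(rid), str(genome), str(contig), genes, pclass))
    return regions


def regions_to_frame(regions: list[BGCRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        for g in r.genes:
            rows.append(
                {
                    "genome_id": r.genome_id,
                    "contig_id": r.contig_id,
                    "region_id": r.region_id,
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "category": g.category,
                    "domains": "|".join(g.domains),
                    "product_class": r.product_class,
                }
            )
    return pd.DataFrame(rows)


def read_gene_table(path) -> list[BGCRegion]:
    """Read a gene table TSV into BGC regions."""
    return regions_from_frame(pd.read_csv(path, sep="\t", dtype=str))


# ------------------------------------------------------------------ matching


def match_blocks(a: BGCRegion, b: BGCRegion, gap_genes: int = 2) -> list[MatchBlock]:
    """Maximal collinear runs of ``a``-genes sharing >= 1 domain family with
    ``b``, merged across gaps of at most ``gap_genes`` unmatched genes.

    Only blocks anchored by a shared core-gene domain family are reported
    (blocks without a core anchor carry no evidence for curation), in
    region-``a`` order.
    """
    b_domains: dict[str, list[int]] = {}
    for j, g in enumerate(b.genes):
        for d in g.domains:
            b_domains.setdefault(d, []).append(j)
    matched_b: list[list[int]] = []
    for g in a.genes:
        hits = sorted({j for d in g.domains for j in b_domains.get(d, [])})
        matched_b.append(hits)
    matched = [bool(h) for h in matched_b]
    blocks: list[MatchBlock] = []
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(a.genes)
    while i < n:
        if not matched[i]:
            i += 1
            continue
        j = i
        last_hit = i
        while j + 1 < n:
            if matched[j + 1]:
                j += 1
                last_hit = j
            elif j + 1 - last_hit <= gap_genes and any(
                matched[k] for k in range(j + 2, min(n, j + 2 + gap_genes))
            ):
                j += 1
            else:
                break
        runs.append((i, last_hit))
        i = last_hit + 1
    for i0, i1 in runs:
        b_hits = sorted({j for k in range(i0, i1 + 1) for j in matched_b[k]})
        if not b_hits:
            continue
        b0, b1 = b_hits[0], b_hits[-1]
        a_core_domains = {
            d for k in range(i0, i1 + 1) if a.genes[k].is_core for d in a.genes[k].domains
        }
        b_core_domains = {
            d for j in range(b0, b1 + 1) if b.genes[j].is_core for d in b.genes[j].domains
        }
        anchor = frozenset(a_core_domains & b_core_domains)
        if anchor:
            blocks.append(MatchBlock(a.region_id, b.region_id, (i0, i1), (b0, b1), anchor))
    return blocks


# ----------------------------------------------------------------- splitting


def split_superclusters(
    gcfs: list[GCF],
    regions: list[BGCRegion],
    gap_genes: int = 2,
    min_core_per_child: int = 1,
) -> tuple[list[BGCRegion], pd.DataFrame]:
    """Split fused regions ("superclusters") using cross-strain evidence.

    A region R in a GCF is split when its core genes partition into >= 2
    disjoint groups, each equal to the core coverage of a match against a
    shorter region from another genome in the same GCF, and the gaps
    between groups contain no core genes.  Children inherit the parent's
    product class; leading/trailing and gap non-core genes are distributed
    so the multiset of genes is conserved.  Returns the revised region list
    and a split log (parent, child, evidence_regions, cut_coordinates).
    """
    by_id = {r.region_id: r for r in regions}
    log_rows = []
    out: list[BGCRegion] = []
    split_ids: set[str] = set()
    new_regions: list[BGCRegion] = []
    for gcf in sorted(gcfs, key=lambda g: g.gcf_id):
        members = [by_id[m] for m in gcf.members if m in by_id]
        for R in sorted(members, key=lambda r: r.region_id):
            if R.region_id in split_ids:
                continue
            core_idx = R.core_indices
            if len(core_idx) < 2 * min_core_per_child:
                continue
            core_set = set(core_idx)
            # candidate groups from shorter regions in other genomes
            candidates: dict[frozenset[int], list[str]] = {}
            for S in members:
                if S.genome_id == R.genome_id or len(S) >= len(R):
                    continue
                blocks = match_blocks(R, S, gap_genes=gap_genes)
                covered = {
                    k
                    for blk in blocks
                    for k in range(blk.a_range[0], blk.a_range[1] + 1)
                    if R.genes[k].is_core
                }
                if not covered or covered == core_set:
                    continue
                if len(covered) < min_core_per_child:
                    continue
                # must be a contiguous run of R's core genes
                pos = sorted(core_idx.index(k) for k in covered)
                if pos != list(range(pos[0], pos[-1] + 1)):
                    continue
                candidates.setdefault(frozenset(covered), []).append(S.region_id)
            if len(candidates) < 2:
                continue
            groups = sorted(candidates, key=min)
            flat: list[int] = []
            for grp in groups:
                flat.extend(sorted(grp))
            if len(set(flat)) != len(flat) or sorted(flat) != flat:
                continue  # overlapping or interleaved evidence: ambiguous, skip
            if set(flat) != core_set:
                continue  # groups must account for every core gene
            # cut in the non-core gap between consecutive groups
            spans = [(min(g), max(g)) for g in groups]
            cuts = []
            ok = True
            for (l0, l1), (r0, r1) in zip(spans, spans[1:]):
                gap = list(range(l1 + 1, r0))
                if any(R.genes[k].is_core for k in gap):
                    ok = False
                    break
                cuts.append(l1 + (len(gap) + 1) // 2)  # last gene index of left child
            if not ok:
                continue
            bounds = [-1] + cuts + [len(R.genes) - 1]
            children = []
            for ci in range(len(groups)):
                genes = R.genes[bounds[ci] + 1 : bounds[ci + 1] + 1]
                children.append(
                    replace(R, region_id=f"{R.region_id}.s{ci + 1}", genes=genes)
                )
            split_ids.add(R.region_id)
            new_regions.extend(children)
            evidence = sorted({s for grp in groups for s in candidates[grp]})
            for ci, child in enumerate(children):
                log_rows.append(
                    {
                        "parent": R.region_id,
                        "child": child.region_id,
                        "evidence_regions": ",".join(evidence),
                        "cut_coordinates": f"{child.interval[0]}-{child.interval[1]}",
                    }
                )
    for r in regions:
        if r.region_id not in split_ids:
            out.append(r)
    out.extend(new_regions)
    log = pd.DataFrame(log_rows, columns=["parent", "child", "evidence_regions",
                                          "cut_coordinates"])
    return out, log


# ------------------------------------------------------------ core reduction


def reduce_to_core(region: BGCRegion) -> BGCRegion | None:
    """Keep only core biosynthetic genes (order preserved, interval shrunk).

    Returns None for a region without core genes (the caller logs and
    excludes it from clustering).  Idempotent.
    """
    core = tuple(g for g in region.genes if g.is_core)
    if not core:
        return None
    return replace(region, genes=core)


def reduce_all_to_core(regions: list[BGCRegion]) -> tuple[list[BGCRegion], list[str]]:
    """Core-reduce every region; returns (reduced, ids of excluded regions)."""
    reduced, excluded = [], []
    for r in regions:
        rr = reduce_to_core(r)
        if rr is None:
            excluded.append(r.region_id)
        else:
            reduced.append(rr)
    return reduced, excluded


# ------------------------------------------------------------------ clustering


def region_distance(a: BGCRegion, b: BGCRegion, w_jaccard: float = 0.7,
                    w_adjacency: float = 0.3) -> float:
    """Stand-in pairwise region distance: 1 − weighted similarity.

    Similarity combines Jaccard of domain sets with Jaccard of domain
    bigrams (adjacency).  When both regions lack bigrams the adjacency term
    is 1 (vacuously identical order); when only one lacks them it is 0.
    """
    da, db = a.domain_set(), b.domain_set()
    union = da | db
    jac = len(da & db) / len(union) if union else 1.0
    ba, bb = a.domain_bigrams(), b.domain_bigrams()
    if not ba and not bb:
        adjacency = 1.0
    elif not ba or not bb:
        adjacency = 0.0
    else:
        adjacency = len(ba & bb) / len(ba | bb)
    return 1.0 - (w_jaccard * jac + w_adjacency * adjacency)


def cluster_gcfs(
    regions: list[BGCRegion],
    cutoff: float = 0.4,
    w_jaccard: float = 0.7,
    w_adjacency: float = 0.3,
) -> list[GCF]:
    """Group regions into GCFs by single-linkage at a distance cutoff.

    Regions connected by edges with distance <= cutoff join one family.
    GCF ids are assigned deterministically by the lexicographically smallest
    member region id, independent of input order.
    """
    if not regions:
        raise PhylolinkError("no regions to cluster")
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate region ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    srt = sorted(regions, key=lambda r: r.region_id)
    for i in range(len(srt)):
        for j in range(i + 1, len(srt)):
            if region_distance(srt[i], srt[j], w_jaccard, w_adjacency) <= cutoff:
                g.add_edge(srt[i].region_id, srt[j].region_id)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [
        GCF(gcf_id=f"GCF_{k + 1:04d}", members=tuple(c)) for k, c in enumerate(comps)
    ]


def gcf_presence_matrix(
    gcfs: list[GCF], regions: list[BGCRegion], strains: list[str]
) -> TraitMatrix:
    """Binary strains x GCFs matrix: 1 iff the strain contributes >= 1 member."""
    genome_of = {r.region_id: r.genome_id for r in regions}
    unknown = sorted(
        {genome_of[m] for g in gcfs for m in g.members if m in genome_of}
        - set(strains)
    )
    if unknown:
        raise PhylolinkError(f"unknown genome id(s): {unknown}")
    data = pd.DataFrame(
        0, index=pd.Index(strains, name="strain_id"),
        columns=[g.gcf_id for g in gcfs], dtype=int,
    )
    for g in gcfs:
        for m in g.members:
            if m not in genome_of:
                raise PhylolinkError(f"GCF {g.gcf_id}: member {m} not among regions")
            data.loc[genome_of[m], g.gcf_id] = 1
    return TraitMatrix(data, "GCF")
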