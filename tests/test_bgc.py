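"""BGC curation: block matching, supercluster splitting, clustering."""

import numpy as np
import pandas as pd
import pytest

from phylolink.bgc import (
    BGCRegion,
    Gene,
    cluster_gcfs,
    gcf_presence_matrix,
    match_blocks,
    reduce_all_to_core,
    reduce_to_core,
    region_distance,
    regions_from_frame,
    regions_to_frame,
    split_superclusters,
)
from phylolink.simulate import synthesize_curation_fixture


def mk_region(rid, genome, spec):
    """spec: list of (category, 'dom1|dom2') tuples."""
    genes = []
    pos = 1
    for i, (cat, doms) in enumerate(spec):
        genes.append(Gene(f"{rid}_g{i}", pos, pos + 999, "+", cat,
                          tuple(doms.split("|")) if doms else ()))
        pos += 1100
    return BGCRegion(rid, genome, "c1", tuple(genes))


class TestMatchBlocks:
    def test_identical_regions_single_full_block(self):
        spec = [("core", "KS|AT"), ("other", "tail"), ("core", "KR")]
        a = mk_region("a", "g1", spec)
        b = mk_region("b", "g2", spec)
        blocks = match_blocks(a, b)
        assert len(blocks) == 1
        assert blocks[0].a_range == (0, 2)
        assert blocks[0].b_range == (0, 2)
        assert "KS" in blocks[0].anchor

    def test_disjoint_domains_no_blocks(self):
        a = mk_region("a", "g1", [("core", "X1"), ("other", "X2")])
        b = mk_region("b", "g2", [("core", "Y1"), ("other", "Y2")])
        assert match_blocks(a, b) == []

    def test_partial_overlap_covers_shared_core_only(self):
        # a = [X-core, filler, Y-core], b = [X-core]: block covers X only
        a = mk_region("a", "g1", [("core", "X"), ("other", "f"), ("core", "Y")])
        b = mk_region("b", "g2", [("core", "X")])
        blocks = match_blocks(a, b)
        assert len(blocks) == 1
        assert blocks[0].a_range == (0, 0)
        assert blocks[0].anchor == frozenset({"X"})


class TestSplitSuperclusters:
    def _fixture_regions(self):
        # genome A fuses blocks X and Y; B carries X; C carries Y
        fused = mk_region("A_r1", "A", [
            ("core", "X_KS|X_AT"), ("core", "X_KS"), ("additional", "X_tail"),
            ("other", "spacer"),
            ("core", "Y_KS|Y_AT"), ("core", "Y_KS"), ("additional", "Y_tail"),
        ])
        bx = mk_region("B_r1", "B", [
            ("core", "X_KS|X_AT"), ("core", "X_KS"), ("additional", "X_tail")])
        cy = mk_region("C_r1", "C", [
            ("core", "Y_KS|Y_AT"), ("core", "Y_KS"), ("additional", "Y_tail")])
        return [fused, bx, cy]

    def test_planted_supercluster_split_into_two(self):
        regions = self._fixture_regions()
        gcfs = cluster_gcfs(regions, cutoff=0.9)
        assert len(gcfs) == 1  # loose cutoff keeps the family together
        revised, log = split_superclusters(gcfs, regions)
        assert sorted(log["parent"].unique()) == ["A_r1"]
        assert len(log) == 2
        children = [r for r in revised if r.region_id.startswith("A_r1.")]
        assert len(children) == 2
        x_child = next(r for r in children if "X_KS" in r.domain_set())
        assert "Y_KS" not in x_child.domain_set()

    def test_gene_multiset_conserved_by_split(self):
        regions = self._fixture_regions()
        gcfs = cluster_gcfs(regions, cutoff=0.9)
        revised, _ = split_superclusters(gcfs, regions)
        before = sorted(g.gene_id for r in regions for g in r.genes)
        after = sorted(g.gene_id for r in revised for g in r.genes)
        assert before == after

    def test_singleton_gcf_unchanged(self):
        fused = self._fixture_regions()[0]
        from phylolink.bgc import GCF

        revised, log = split_superclusters(
            [GCF("GCF_0001", (fused.region_id,))], [fused])
        assert log.empty
        assert revised == [fused]

    def test_full_length_members_no_split(self):
        spec = [("core", "X_KS"), ("other", "mid"), ("core", "Y_KS")]
        regions = [mk_region("A_r1", "A", spec), mk_region("B_r1", "B", spec)]
        gcfs = cluster_gcfs(regions, cutoff=0.9)
        _, log = split_superclusters(gcfs, regions)
        assert log.empty

    def test_generated_fixtures_recovered_exactly(self):
        """Planted superclusters recovered, and distractor-only fixtures
        produce no splits, across randomized fixtures."""
        for seed in range(10):
            genes, expected = synthesize_curation_fixture(
                seed=seed, n_superclusters=2, n_distractors=3)
            regions = regions_from_frame(genes)
            gcfs = cluster_gcfs(regions, cutoff=0.9)
            revised, log = split_superclusters(gcfs, regions)
            assert sorted(log["parent"].unique()) == sorted(
                expected["parent"].unique())
            assert len(log) == len(expected)
        genes, expected = synthesize_curation_fixture(
            seed=0, n_superclusters=0, n_distractors=4)
        regions = regions_from_frame(genes)
        gcfs = cluster_gcfs(regions, cutoff=0.9)
        _, log = split_superclusters(gcfs, regions)
        assert log.empty and expected.empty


class TestReduceToCore:
    def test_keeps_only_core_genes(self):
        r = mk_region("r", "g", [("core", "a"), ("other", "b"), ("core", "c"),
                                 ("transport", "d"), ("regulatory", "e")])
        rr = reduce_to_core(r)
        assert [g.category for g in rr.genes] == ["core", "core"]

    def test_region_without_core_excluded_and_logged(self):
        r = mk_region("r", "g", [("other", "a"), ("transport", "b")])
        assert reduce_to_core(r) is None
        reduced, excluded = reduce_all_to_core([r])
        assert reduced == [] and excluded == ["r"]

    def test_idempotent(self):
        r = mk_region("r", "g", [("core", "a"), ("other", "b"), ("core", "c")])
        once = reduce_to_core(r)
        assert reduce_to_core(once) == once


class TestClusterGCFs:
    def test_identical_regions_same_family(self):
        spec = [("core", "KS|AT"), ("other", "t")]
        gcfs = cluster_gcfs([mk_region("a", "g1", spec), mk_region("b", "g2", spec)])
        assert len(gcfs) == 1
        assert region_distance(mk_region("a", "g1", spec),
                               mk_region("b", "g2", spec)) == 0.0

    def test_disjoint_regions_separate_families(self):
        a = mk_region("a", "g1", [("core", "X1|X2")])
        b = mk_region("b", "g2", [("core", "Y1|Y2")])
        assert region_distance(a, b) == 1.0
        assert len(cluster_gcfs([a, b], cutoff=0.4)) == 2

    def test_raising_cutoff_never_increases_family_count(self, rng):
        """More edges can only merge components: the family count at a higher
        cutoff is <= the count at a lower one (the direction of the reported
        cutoff sweep)."""
        pool = ["KS", "AT", "KR", "DH", "ER", "MT", "TE", "A", "C", "PCP"]
        regions = []
        for i in range(25):
            doms = rng.choice(pool, size=rng.integers(2, 6), replace=False)
            spec = [("core", "|".join(doms[:2]))] + [
                ("other", d) for d in doms[2:]]
            regions.append(mk_region(f"r{i:02d}", f"g{i:02d}", spec))
        counts = [len(cluster_gcfs(regions, cutoff=c)) for c in (0.3, 0.4, 0.5)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_input_order_invariance(self, rng):
        pool = ["KS", "AT", "KR", "DH", "ER"]
        regions = []
        for i in range(12):
            doms = rng.choice(pool, size=3, replace=False)
            regions.append(mk_region(f"r{i:02d}", f"g{i:02d}",
                                     [("core", "|".join(doms))]))
        ids1 = [(g.gcf_id, g.members) for g in cluster_gcfs(regions)]
        shuffled = list(regions)
        rng.shuffle(shuffled)
        ids2 = [(g.gcf_id, g.members) for g in cluster_gcfs(shuffled)]
        assert ids1 == ids2


class TestPresenceMatrix:
    def test_membership_column(self):
        from phylolink.bgc import GCF

        regions = [mk_region("rA", "A", [("core", "x")]),
                   mk_region("rB", "B", [("core", "x")])]
        gcfs = [GCF("GCF_0001", ("rA", "rB"))]
        m = gcf_presence_matrix(gcfs, regions, ["A", "B", "C"])
        assert list(m.data["GCF_0001"]) == [1, 1, 0]

    def test_empty_gcf_list_zero_columns(self):
        regions = [mk_region("rA", "A", [("core", "x")])]
        m = gcf_presence_matrix([], regions, ["A"])
        assert m.shape == (1, 0)

    def test_two_regions_same_strain_still_binary(self):
        from phylolink.bgc import GCF

        regions = [mk_region("r1", "A", [("core", "x")]),
                   mk_region("r2", "A", [("core", "x")])]
        m = gcf_presence_matrix([GCF("GCF_0001", ("r1", "r2"))], regions, ["A", "B"])
        assert list(m.data["GCF_0001"]) == [1, 0]

    def test_unknown_genome_rejected(self):
        from phylolink.bgc import GCF
        from phylolink.io import PhylolinkError

        regions = [mk_region("rA", "A", [("core", "x")])]
        with pytest.raises(PhylolinkError):
            gcf_presence_matrix([GCF("GCF_0001", ("rA",))], regions, ["B"])


def test_gene_table_round_trip():
    genes, _ = synthesize_curation_fixture(seed=5, n_superclusters=1)
    regions = regions_from_frame(genes)
    back = regions_from_frame(regions_to_frame(regions))
    assert sorted(r.region_id for r in back) == sorted(r.region_id for r in regions)
    assert sum(len(r) for r in back) == sum(len(r) for r in regions)
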