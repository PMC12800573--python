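"""Association screens, eligibility, known-pair evaluation, permutations."""

import numpy as np
import pandas as pd
import pytest

from phylolink.association import (
    associate_all,
    chisq_screen,
    evaluate_known_pairs,
    parsimony_changes,
    permutation_control,
    results_to_frame,
    _chisq_oracle,
)
from phylolink.io import KnownPairCatalog, Phylogeny, TraitMatrix
from phylolink.simulate import SimulationConfig, synthesize_dataset


class TestParsimony:
    def test_constant_trait_zero_changes(self, balanced4):
        assert parsimony_changes(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0

    def test_two_sister_tips_single_gain(self):
        # presence confined to one cherry: a single gain explains it
        tree = Phylogeny.from_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        assert parsimony_changes(tree, {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}) == 1

    def test_alternating_pattern_two_changes(self, balanced4):
        assert parsimony_changes(balanced4, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_multifurcation(self):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert parsimony_changes(tree, {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}) == 2


class TestChisqScreen:
    def _mats(self, G, M):
        strains = [f"s{i}" for i in range(G.shape[0])]
        return (
            TraitMatrix(pd.DataFrame(G, index=strains,
                                     columns=[f"g{j}" for j in range(G.shape[1])]), "GCF"),
            TraitMatrix(pd.DataFrame(M, index=strains,
                                     columns=[f"m{j}" for j in range(M.shape[1])]), "MF"),
        )

    def test_matches_scipy_contingency_oracle(self, rng):
        """The vectorised statistic equals scipy's chi2_contingency with and
        without continuity correction on random non-degenerate tables."""
        for _ in range(20):
            g = rng.integers(0, 2, size=(40, 1))
            m = rng.integers(0, 2, size=(40, 1))
            if g.min() == g.max() or m.min() == m.max():
                continue
            gv, mv = g[:, 0], m[:, 0]
            table = np.array(
                [[int((gv * mv).sum()), int((gv * (1 - mv)).sum())],
                 [int(((1 - gv) * mv).sum()), int(((1 - gv) * (1 - mv)).sum())]]
            )
            for cont in (True, False):
                gm, mm = self._mats(g, m)
                res = chisq_screen(gm, mm, continuity=cont)[0]
                stat, p = _chisq_oracle(table[::-1, ::-1], continuity=cont)
                assert abs(res.D - stat) < 1e-9
                assert abs(res.p - p) < 1e-12

    def test_strong_association_table(self):
        # 30 co-present, 32 co-absent, 5+5 discordant of 72 strains:
        # uncorrected chi2 = 72*(30*32-5*5)^2/(35*37*35*37) = 37.533
        g = np.r_[np.ones(35, dtype=int), np.zeros(37, dtype=int)]
        m = np.r_[np.ones(30, dtype=int), np.zeros(5, dtype=int),
                  np.ones(5, dtype=int), np.zeros(32, dtype=int)]
        gm, mm = self._mats(g[:, None], m[:, None])
        res_u = chisq_screen(gm, mm, continuity=False)[0]
        assert abs(res_u.D - 37.53325084599216) < 1e-9
        res_c = chisq_screen(gm, mm, continuity=True)[0]
        assert res_c.D < res_u.D  # correction shrinks the statistic
        assert abs(res_c.D - 34.698631207048194) < 1e-9
        assert res_c.verdict == "linked"  # p << 0.01, positive direction

    def test_proportional_table_not_linked(self):
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0])[:, None]
        m = np.array([1, 1, 0, 0, 1, 1, 0, 0])[:, None]
        gm, mm = self._mats(g, m)
        res = chisq_screen(gm, mm, continuity=False)[0]
        assert res.D == 0.0
        assert res.verdict == "not-linked"

    def test_anti_association_rejected_by_direction_filter(self):
        g = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)][:, None]
        m = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)][:, None]
        gm, mm = self._mats(g, m)
        res = chisq_screen(gm, mm)[0]
        assert res.p < 0.01  # overwhelming (anti-)signal
        assert res.verdict == "not-linked"
        res_nf = chisq_screen(gm, mm, direction_filter=False)[0]
        assert res_nf.verdict == "linked"

    def test_constant_trait_flagged(self):
        g = np.zeros((10, 1), dtype=int)
        m = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)][:, None]
        gm, mm = self._mats(g, m)
        res = chisq_screen(gm, mm)[0]
        assert res.verdict == "not-linked" and res.flagged

    def test_strain_order_invariance(self, rng):
        g = rng.integers(0, 2, size=(30, 3))
        m = rng.integers(0, 2, size=(30, 2))
        gm, mm = self._mats(g, m)
        perm = rng.permutation(30)
        gm2 = TraitMatrix(gm.data.iloc[perm], "GCF")
        mm2 = TraitMatrix(mm.data.iloc[perm], "MF")
        r1 = results_to_frame(chisq_screen(gm, mm))
        r2 = results_to_frame(chisq_screen(gm2, mm2))
        pd.testing.assert_frame_equal(r1, r2)


@pytest.fixture(scope="module")
def small_truth():
    return synthesize_dataset(
        SimulationConfig(
            n_strains=40, n_gcf_traits=8, n_mf_traits=5, n_linked_pairs=2,
            min_events=4, seed=21,
        )
    )


class TestAssociateAll:
    def test_ineligible_pairs_never_linked(self, small_truth):
        res = associate_all(small_truth.gcf, small_truth.mf, small_truth.tree,
                            seed=0, n_restarts=2)
        for r in res:
            if r.changes_gcf < 2 or r.changes_mf < 2:
                assert r.verdict == "ineligible"
            if r.verdict == "linked":
                assert r.eligible and r.p < 0.01 and r.rq >= 0.65
                assert r.D >= 0

    def test_deterministic_given_seed(self, small_truth):
        kw = dict(seed=5, n_restarts=2)
        r1 = results_to_frame(
            associate_all(small_truth.gcf, small_truth.mf, small_truth.tree, **kw))
        r2 = results_to_frame(
            associate_all(small_truth.gcf, small_truth.mf, small_truth.tree, **kw))
        pd.testing.assert_frame_equal(r1, r2)

    def test_mismatched_strains_rejected(self, small_truth):
        bad = TraitMatrix(small_truth.gcf.data.iloc[:-1], "GCF")
        with pytest.raises(Exception, match="strain"):
            associate_all(bad, small_truth.mf, small_truth.tree, seed=0)


class TestEvaluateKnownPairs:
    def _res(self, links, method="phylo", ineligible_mfs=()):
        from phylolink.association import AssociationResult

        out = []
        for g, m in links:
            out.append(AssociationResult(gcf_id=g, mf_id=m, method=method,
                                         verdict="linked", eligible=True))
        for m in ineligible_mfs:
            out.append(AssociationResult(gcf_id="gX", mf_id=m, method=method,
                                         verdict="ineligible", eligible=False))
        return out

    def _catalog(self, pairs):
        return KnownPairCatalog(pd.DataFrame(
            {"compound": [f"c{i}" for i in range(len(pairs))],
             "gcf_id": [p[0] for p in pairs], "mf_id": [p[1] for p in pairs]}))

    def test_correct_and_false_positive_counting(self):
        cat = self._catalog([("G1", "M1")])
        summary = evaluate_known_pairs(self._res([("G1", "M1"), ("G2", "M1")]), cat)
        assert summary.n_correct == 1
        assert summary.n_false_positives == 1

    def test_empty_predictions(self):
        cat = self._catalog([("G1", "M1")])
        summary = evaluate_known_pairs(self._res([]), cat)
        assert summary.n_correct == 0 and summary.n_false_positives == 0

    def test_links_outside_catalog_ignored(self):
        cat = self._catalog([("G1", "M1")])
        summary = evaluate_known_pairs(
            self._res([("G1", "M1"), ("G5", "M9"), ("G6", "M8")]), cat)
        assert summary.n_correct == 1 and summary.n_false_positives == 0

    def test_fold_reduction_excludes_unassessed_compounds(self):
        """A compound whose MF was ineligible for the primary method drops
        out of the comparator's false-positive baseline."""
        cat = self._catalog([("G1", "M1"), ("G2", "M2")])
        phylo = self._res([("G1", "M1")], ineligible_mfs=["M2"])
        # comparator: 3 FPs on M1, 14 FPs on M2 (the excluded compound)
        chis = self._res(
            [("G1", "M1")] + [(f"Gf{i}", "M1") for i in range(3)]
            + [(f"Gh{i}", "M2") for i in range(14)],
            method="chisq",
        )
        summary = evaluate_known_pairs(phylo, cat, comparator=chis)
        assert summary.comparator_false_positives == 3  # M2's 14 excluded
        assert np.isinf(summary.fold_reduction)  # phylo had 0 FPs


class TestPermutationControl:
    def test_permutation_preserves_column_sums_and_destroys_links(self, small_truth):
        cat = KnownPairCatalog(pd.DataFrame({
            "compound": ["c1", "c2"],
            "gcf_id": small_truth.linked_pairs["gcf_id"],
            "mf_id": small_truth.linked_pairs["mf_id"],
        }))
        records = permutation_control(
            small_truth.gcf, small_truth.mf, small_truth.tree, cat,
            n_perm=3, seed=4, methods=("chisq",),
        )
        assert len(records) == 3
        for rec in records:
            assert "seed" in rec
            assert rec["chisq"].n_correct <= 1  # signal essentially destroyed
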