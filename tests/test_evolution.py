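"""NG86 selection analysis, patristic distances, RBH and synteny."""

import random
import warnings

import dendropy
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evescreen.evolution import (CodonAlignmentPair, back_translate_alignment,
                                 codon_pair_from_proteins,
                                 family_distance_summary, ng86_dnds,
                                 patristic_matrix, purifying_screen,
                                 reciprocal_best_hits, synteny_orders)
from evescreen.simulate import _random_sense_codons, _rng, evolve_codons


def random_cds(n_codons, seed):
    return "ATG" + "".join(_random_sense_codons(_rng(seed), n_codons - 1, 0.5))


class TestBackTranslate:
    def test_gap_expands_to_codon_gap(self):
        rows = back_translate_alignment(
            [("p1", "M-K"), ("p2", "MGK")],
            {"p1": "ATGAAATAA", "p2": "ATGGGTAAA"},
        )
        assert rows == [("p1", "ATG---AAA"), ("p2", "ATGGGTAAA")]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            back_translate_alignment([("p1", "MK")], {"p1": "ATGTAAAAA"})

    def test_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            back_translate_alignment([("p1", "MK")], {"p1": "ATGGGG"})

    def test_round_trip(self):
        from evescreen.homology import translate_frame
        cds = random_cds(40, 3)
        prot = translate_frame(cds, 0)
        (row,) = back_translate_alignment([("p", prot)], {"p": cds})
        assert row[1] == cds


class TestNg86:
    def test_identical_sequences_zero_distance(self):
        cds = random_cds(100, 1)
        res = ng86_dnds(CodonAlignmentPair("a", "b", cds, cds))
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.omega is None and "omega_undefined_dS_zero" in res.flags

    def test_single_synonymous_difference_hand_count(self):
        # TTT -> TTC (both Phe) in an otherwise identical context:
        # one synonymous difference, zero nonsynonymous
        ctx = "ATG" + "GCT" * 8
        res = ng86_dnds(CodonAlignmentPair("a", "b", ctx + "TTT", ctx + "TTC"))
        assert (res.Sd, res.Nd) == (1.0, 0.0)
        assert res.dN == 0.0 and res.dS > 0.0
        assert res.omega == pytest.approx(0.0)
        assert res.purifying is True

    def test_one_codon_pair_saturates_correction(self):
        res = ng86_dnds(CodonAlignmentPair("a", "b", "TTT", "TTC"))
        assert res.dS is None and "dS_saturated" in res.flags

    def test_site_counts_sum_to_three_per_codon(self):
        cds = random_cds(200, 5)
        mut, _ = evolve_codons(cds, 0.5, 0.3, seed=1)
        res = ng86_dnds(CodonAlignmentPair("a", "b", cds, mut))
        assert res.S_sites + res.N_sites == pytest.approx(3 * res.n_codons)

    def test_matches_independent_reference_implementation(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in (1, 2, 3):
            cds = random_cds(300, seed)
            mut, _ = evolve_codons(cds, 0.4, 0.4, seed=seed + 10)
            mine = ng86_dnds(CodonAlignmentPair("a", "b", cds, mut))
            dn, ds = cal_dn_ds(CodonSeq(cds), CodonSeq(mut), method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)

    def test_column_permutation_invariance(self):
        cds = random_cds(120, 7)
        mut, _ = evolve_codons(cds, 0.5, 0.4, seed=8)
        res = ng86_dnds(CodonAlignmentPair("a", "b", cds, mut))
        rng = np.random.default_rng(0)
        order = rng.permutation(len(cds) // 3)
        shuf_a = "".join(cds[3 * i : 3 * i + 3] for i in order)
        shuf_b = "".join(mut[3 * i : 3 * i + 3] for i in order)
        res2 = ng86_dnds(CodonAlignmentPair("a", "b", shuf_a, shuf_b))
        assert res2.dN == pytest.approx(res.dN)
        assert res2.dS == pytest.approx(res.dS)

    def test_symmetric_in_arguments(self):
        cds = random_cds(150, 9)
        mut, _ = evolve_codons(cds, 0.5, 0.4, seed=11)
        a = ng86_dnds(CodonAlignmentPair("x", "y", cds, mut))
        b = ng86_dnds(CodonAlignmentPair("y", "x", mut, cds))
        assert a.dN == pytest.approx(b.dN) and a.dS == pytest.approx(b.dS)

    def test_gapped_columns_excluded(self):
        pair = CodonAlignmentPair("a", "b", "ATGAAA---TTT", "ATGAAAGGGTTT")
        res = ng86_dnds(pair)
        assert res.n_codons == 3

    def test_whole_codon_gap_rule_enforced(self):
        with pytest.raises(ValueError, match="whole-codon"):
            CodonAlignmentPair("a", "b", "ATGA--AAA", "ATGAAAAAA")


class TestPurifyingScreen:
    def _result(self, omega):
        cds = random_cds(60, 2)
        res = ng86_dnds(CodonAlignmentPair("a", "b", cds, cds))
        res.omega = omega
        return res

    def test_flags_and_counts(self):
        results = [self._result(0.3), self._result(1.2), self._result(None)]
        screen = purifying_screen(results)
        assert screen["flags"] == [True, False, None]
        assert (screen["n_purifying"], screen["n_not_purifying"],
                screen["n_undefined"]) == (1, 1, 1)

    def test_cohort_flags_match_generator_truth(self):
        flags = []
        for rep in range(30):
            omega_true = 0.2 if rep % 2 == 0 else 2.0
            cds = random_cds(400, 100 + rep)
            mut, _ = evolve_codons(cds, omega_true, 0.4, seed=(rep,))
            flags.append(
                (omega_true < 1,
                 ng86_dnds(CodonAlignmentPair("a", "b", cds, mut)).purifying)
            )
        correct = sum(1 for truth, got in flags if truth == got)
        assert correct >= 28  # >= ~93% on a modest cohort


class TestPatristic:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_small_tree_path_sums(self):
        m = patristic_matrix(self._tree("((A:1,B:2):3,C:4);"))
        assert m.at["A", "B"] == pytest.approx(3.0)
        assert m.at["A", "C"] == pytest.approx(8.0)
        assert m.at["B", "C"] == pytest.approx(9.0)
        assert (np.diag(m.values) == 0).all()

    def test_star_tree_equal_distances(self):
        m = patristic_matrix(self._tree("(A:2,B:2,C:2,D:2);"))
        off = m.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 4.0)

    def test_matches_shortest_path_oracle_on_random_tree(self):
        tree = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.5, num_extant_tips=20, rng=random.Random(3)
        )
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
        m = patristic_matrix(tree)
        graph = nx.Graph()
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None:
                graph.add_edge(id(e.tail_node), id(e.head_node), weight=e.length)
        leaves = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
        for a in m.index:
            for b in m.columns:
                expected = 0.0 if a == b else nx.shortest_path_length(
                    graph, leaves[a], leaves[b], weight="weight")
                assert m.at[a, b] == pytest.approx(expected)

    def test_four_point_condition_on_random_quartets(self):
        tree = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.3, num_extant_tips=12, rng=random.Random(7)
        )
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.1
        m = patristic_matrix(tree)
        rng = random.Random(0)
        labels = list(m.index)
        for _ in range(25):
            i, j, k, l = rng.sample(labels, 4)
            sums = sorted([m.at[i, j] + m.at[k, l],
                           m.at[i, k] + m.at[j, l],
                           m.at[i, l] + m.at[j, k]])
            assert sums[1] == pytest.approx(sums[2], rel=1e-9)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch lengths"):
            patristic_matrix(self._tree("((A:1,B),C:4);"))


class TestFamilyDistances:
    def test_hand_enumerated_two_families(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):4,(C:1,D:1):4);",
                                 schema="newick")
        m = patristic_matrix(tree)
        summary = family_distance_summary(
            m, {"A": "f1", "B": "f1", "C": "f2", "D": "f2"})
        assert summary.within["f1"]["mean"] == pytest.approx(2.0)
        assert summary.pooled_between["min"] == pytest.approx(10.0)
        assert summary.pooled_between["n_pairs"] == 4

    def test_single_family_no_between(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        m = patristic_matrix(tree)
        summary = family_distance_summary(m, dict.fromkeys("ABC", "f"))
        assert summary.pooled_between is None
        assert summary.pooled_within["n_pairs"] == 3

    def test_clustered_clades_separate_cleanly(self):
        # family-clustered clades on a long internal branch: pooled
        # within-family max below pooled between-family min
        tree = dendropy.Tree.get(
            data="((A:0.2,B:0.3):5,(C:0.1,D:0.4):5);", schema="newick")
        m = patristic_matrix(tree)
        summary = family_distance_summary(
            m, {"A": "f1", "B": "f1", "C": "f2", "D": "f2"})
        assert summary.pooled_within["max"] < summary.pooled_between["min"]


class TestReciprocalBestHits:
    class Hit:
        def __init__(self, q, s, bits, evalue=1e-10):
            self.query_id, self.scaffold_id = q, s
            self.bitscore, self.evalue = bits, evalue

    def test_symmetric_unique_bests_all_kept(self):
        ab = [self.Hit("a1", "b1", 100), self.Hit("a2", "b2", 90)]
        ba = [self.Hit("b1", "a1", 100), self.Hit("b2", "a2", 90)]
        assert reciprocal_best_hits(ab, ba) == [("a1", "b1"), ("a2", "b2")]

    def test_non_reciprocal_pair_dropped(self):
        ab = [self.Hit("a1", "b1", 100)]
        ba = [self.Hit("b1", "a2", 100)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_swap_symmetry_and_brute_force(self):
        rng = np.random.default_rng(4)
        n_a, n_b = 8, 7
        ab, ba = [], []
        score = rng.integers(10, 500, size=(n_a, n_b))
        for i in range(n_a):
            for j in range(n_b):
                ab.append(self.Hit(f"a{i}", f"b{j}", float(score[i, j])))
                ba.append(self.Hit(f"b{j}", f"a{i}", float(score[i, j])))
        pairs = reciprocal_best_hits(ab, ba)
        swapped = {(a, b) for b, a in reciprocal_best_hits(ba, ab)}
        assert set(pairs) == swapped
        # brute force over the score matrix (ties: smaller subject id)
        expected = []
        for i in range(n_a):
            best_j = min(range(n_b), key=lambda j: (-score[i, j], f"b{j}"))
            best_i = min(range(n_a), key=lambda k: (-score[k, best_j], f"a{k}"))
            if best_i == i:
                expected.append((f"a{i}", f"b{best_j}"))
        assert pairs == sorted(expected)


class TestSynteny:
    GENES_A = [("g1", 100, "+"), ("g2", 500, "+"), ("g3", 900, "-")]

    def test_identical_order_is_diagonal(self):
        genes_b = [("h1", 50, "+"), ("h2", 60, "+"), ("h3", 70, "-")]
        points = synteny_orders(self.GENES_A, genes_b,
                                [("g1", "h1"), ("g2", "h2"), ("g3", "h3")])
        assert [(p.rank_a, p.rank_b) for p in points] == [(1, 1), (2, 2), (3, 3)]
        assert all(p.same_strand for p in points)

    def test_reversed_order_is_antidiagonal(self):
        genes_b = [("h1", 300, "+"), ("h2", 200, "+"), ("h3", 100, "-")]
        points = synteny_orders(self.GENES_A, genes_b,
                                [("g1", "h1"), ("g2", "h2"), ("g3", "h3")])
        assert [(p.rank_a, p.rank_b) for p in points] == [(1, 3), (2, 2), (3, 1)]

    def test_random_permutation_recovered(self):
        rng = np.random.default_rng(5)
        n = 12
        genes_a = [(f"g{i}", 100 * (i + 1), "+") for i in range(n)]
        perm = rng.permutation(n)
        genes_b = [(f"h{i}", 100 * (int(perm[i]) + 1), "+") for i in range(n)]
        pairs = [(f"g{i}", f"h{i}") for i in range(n)]
        points = synteny_orders(genes_a, genes_b, pairs)
        assert [p.rank_b for p in points] == [int(perm[i]) + 1 for i in range(n)]

    def test_duplicate_gene_rejected(self):
        genes_b = [("h1", 50, "+"), ("h2", 60, "+"), ("h3", 70, "-")]
        with pytest.raises(ValueError, match="twice"):
            synteny_orders(self.GENES_A, genes_b, [("g1", "h1"), ("g1", "h2")])
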