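"""Similarity graph, Markov clustering, cluster categorization, clade pairs."""

import networkx as nx
import numpy as np
import pytest

from orphanscan.clustering import (
    build_clade_pairs,
    build_graph,
    categorize_clusters,
    markov_cluster,
    smith_waterman,
)


def sw_oracle(a, b, match, mismatch, gap):
    """Brute-force Smith-Waterman with linear gaps (all cells, max score)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    return H.max()


class TestSmithWaterman:
    def test_self_alignment_equals_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        b62 = substitution_matrices.load("BLOSUM62")
        seq = "MKTAYIAKQR"
        expected = sum(b62[c, c] for c in seq)
        assert smith_waterman(seq, seq) == pytest.approx(expected)

    def test_matches_bruteforce_dp_oracle(self):
        a, b = "TGTTACGG", "GGTTGACTA"
        oracle = sw_oracle(a, b, match=3, mismatch=-3, gap=-2)
        got = smith_waterman(a, b, match=3, mismatch=-3, gap_open=2,
                             gap_extend=2)
        assert got == pytest.approx(oracle)

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 12)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 12)))
            oracle = sw_oracle(a, b, 2, -1, -2)
            got = smith_waterman(a, b, match=2, mismatch=-1, gap_open=2,
                                 gap_extend=2)
            assert got == pytest.approx(oracle), (a, b)

    def test_no_positive_pair_scores_zero(self):
        assert smith_waterman("AAAA", "TTTT", match=1, mismatch=-2,
                              gap_open=2, gap_extend=2) == 0.0

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("MK1", "MK")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "MK")


class TestBuildGraph:
    def test_threshold_above_one_gives_no_edges(self):
        prots = {"a": "MKTAYIAK", "b": "MKTAYIAK"}
        g = build_graph(prots, min_normalized_score=1.5)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_identical_proteins_fully_connected_at_zero_threshold(self):
        prots = {"a": "MKTAYIAKQRQISFVK", "b": "MKTAYIAKQRQISFVK",
                 "c": "MKTAYIAKQRQISFVK"}
        g = build_graph(prots, min_normalized_score=0.0)
        assert g.number_of_edges() == 3

    def test_planted_families_give_two_components(self, small_dataset):
        # two truth clusters from the generator: members within a cluster are
        # near-identical, across clusters unrelated
        ds = small_dataset
        cids = sorted(ds.truth.clusters)[:2]
        prots = {}
        for cid in cids:
            rec = ds.truth.clusters[cid]
            gid = rec["members"][0]
            xid = rec["members"][-1]
            prots[gid] = ds.genes[gid].protein
            prots[xid] = ds.pex_proteins[xid]
        g = build_graph(prots, min_normalized_score=0.3)
        comps = list(nx.connected_components(g))
        assert len(comps) == 2


class TestMarkovCluster:
    @staticmethod
    def mcl_oracle(adj, nodes, inflation=2.0):
        """Naive expansion/inflation iteration to fixpoint (dense loops)."""
        n = len(nodes)
        M = adj.copy().astype(float)
        for i in range(n):
            M[i, i] = max(M[i, i], 1.0)
        M = M / M.sum(axis=0)
        for _ in range(200):
            M = M @ M
            M = M**inflation
            M = M / M.sum(axis=0)
            M[M < 1e-5] = 0.0
            M = M / M.sum(axis=0)
        clusters = set()
        for i in range(n):
            if M[i, i] > 1e-5:
                clusters.add(frozenset(nodes[j] for j in np.nonzero(M[i] > 1e-5)[0]))
        return {frozenset(c) for c in clusters}

    def test_two_disjoint_cliques(self):
        g = nx.Graph()
        for clique in (["a", "b", "c"], ["x", "y", "z"]):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(clique[i], clique[j], weight=1.0)
        clusters, converged = markov_cluster(g)
        assert converged
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_isolated_node_singleton(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("lonely")
        clusters, _ = markov_cluster(g)
        assert ["lonely"] in clusters

    def test_barbell_matches_naive_oracle(self):
        # clique {A,B,C} - bridge C-D - clique {D,E}
        g = nx.Graph()
        for u, v in [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
                     ("D", "E")]:
            g.add_edge(u, v, weight=1.0)
        nodes = sorted(g.nodes)
        adj = nx.to_numpy_array(g, nodelist=nodes)
        expected = self.mcl_oracle(adj, nodes)
        clusters, _ = markov_cluster(g, inflation=2.0)
        assert {frozenset(c) for c in clusters} == expected
        assert {frozenset(c) for c in clusters} == {
            frozenset({"A", "B", "C"}),
            frozenset({"D", "E"}),
        }

    def test_partition_property(self, small_dataset):
        ds = small_dataset
        prots = {g: m.protein for g, m in ds.genes.items()}
        prots.update(ds.pex_proteins)
        g = build_graph(prots)
        clusters, _ = markov_cluster(g)
        flat = [x for c in clusters for x in c]
        assert len(flat) == len(set(flat)) == len(prots)

    def test_invalid_inflation(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            markov_cluster(g, inflation=1.0)


class TestCategorize:
    labels = {"g1": True, "g2": False, "g3": True, "g4": True, "g5": False}
    species = {**{f"g{i}": "ppa" for i in range(1, 6)},
               **{f"x{i}": "pex" for i in range(1, 4)}}

    def test_orphan_ortholog_pair(self):
        recs, excl = categorize_clusters([["g1", "x1"]], self.labels,
                                         self.species)
        assert recs[0].category == "orphan"
        assert recs[0].in_ortholog and not recs[0].in_paralog
        assert excl.empty

    def test_hybrid_excluded(self):
        recs, excl = categorize_clusters(
            [["g1", "g2", "x1"]], self.labels, self.species
        )
        assert recs[0].category == "hybrid"
        assert not recs[0].in_ortholog and not recs[0].in_paralog
        assert list(excl["category"]) == ["hybrid"]

    def test_pex_specific_excluded(self):
        recs, excl = categorize_clusters([["x1", "x2"]], self.labels,
                                         self.species)
        assert recs[0].category == "pex_specific"
        assert list(excl["category"]) == ["pex_specific"]

    def test_cluster_in_both_datasets(self):
        recs, _ = categorize_clusters(
            [["g1", "g3", "g4", "x1"]], self.labels, self.species
        )
        rec = recs[0]
        assert rec.in_ortholog and rec.in_paralog
        assert sorted(rec.ppa_members) == ["g1", "g3", "g4"]

    def test_unlabeled_gene_rejected(self):
        with pytest.raises(ValueError):
            categorize_clusters([["g9"]], self.labels, {"g9": "ppa"})


class TestCladePairs:
    def test_no_variants_identical_pair(self, small_dataset):
        import pandas as pd

        ds = small_dataset
        empty = pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
        pairs = build_clade_pairs(ds.genes, empty, empty)
        for aln in pairs.values():
            assert aln.rows[0] == aln.rows[1]

    def test_pair_count_equals_gene_count(self, small_dataset):
        ds = small_dataset
        pairs = build_clade_pairs(ds.genes, ds.variants_a1, ds.variants_a2)
        assert len(pairs) == len(ds.genes)

    def test_single_difference_hamming_one(self, small_dataset):
        import pandas as pd

        ds = small_dataset
        # take the first A1 variant and apply it alone
        row = ds.variants_a1.iloc[[0]]
        empty = pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
        pairs = build_clade_pairs(ds.genes, row, empty)
        hamming = {
            gid: sum(1 for a, b in zip(aln.rows[0], aln.rows[1]) if a != b)
            for gid, aln in pairs.items()
        }
        assert sum(hamming.values()) == 1
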