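"""Evidence integration: dataset flags, Venn regions, classes, candidates,
feature statistics."""

import numpy as np
import pandas as pd
import pytest

from orphanscan.evidence import (
    classify,
    contig_percentile,
    feature_stats,
    gene_selection_evidence,
    omega_cumulative_curve,
    rank_sum_test,
    select_validation_candidates,
    venn3,
)
from orphanscan.records import RunConfig


def _selection_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "omega", "q_value", "significant"],
    )
    return df


class TestGeneSelectionEvidence:
    def _evidence(self, omega, q, sig, dataset="ortholog"):
        selection = {
            dataset: _selection_frame([("c1", omega, q, sig)]),
        }
        memberships = {dataset: {"c1": ["g1"]}}
        return gene_selection_evidence(selection, memberships, ["g1", "g2"])

    def test_liberal_only(self):
        ev = self._evidence(0.55, 0.5, False)
        assert ev.loc["g1", "liberal_any"]
        assert not ev.loc["g1", "conservative_any"]

    def test_conservative_without_liberal(self):
        ev = self._evidence(0.9, 0.01, True)
        assert ev.loc["g1", "conservative_any"]
        assert not ev.loc["g1", "liberal_any"]

    def test_no_coverage(self):
        ev = self._evidence(0.5, 0.01, True)
        assert ev.loc["g2", "selection_coverage"] == 0
        assert not ev.loc["g2", "liberal_any"]
        assert not ev.loc["g2", "conservative_any"]

    def test_partition_violation_rejected(self):
        selection = {
            "ortholog": _selection_frame(
                [("c1", 0.5, 0.01, True), ("c2", 0.7, 0.2, False)]
            )
        }
        memberships = {"ortholog": {"c1": ["g1"], "c2": ["g1"]}}
        with pytest.raises(ValueError, match="partition"):
            gene_selection_evidence(selection, memberships, ["g1"])


class TestVenn3:
    def test_disjoint(self):
        regions = venn3({"A": {1}, "B": {2}, "C": {3}})
        assert regions["A"] == regions["B"] == regions["C"] == 1
        assert regions["A&B"] == regions["A&B&C"] == 0

    def test_identical(self):
        regions = venn3({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert regions["A&B&C"] == 2
        assert sum(v for k, v in regions.items() if k != "A&B&C") == 0

    def test_enumerated_example(self):
        regions = venn3({"A": {1, 2}, "B": {2, 3}, "C": {3}})
        assert regions["A"] == 1
        assert regions["A&B"] == 1
        assert regions["B&C"] == 1
        assert regions["B"] == regions["C"] == 0
        assert regions["A&C"] == 0 and regions["A&B&C"] == 0

    def test_regions_sum_to_set_sizes(self):
        rng = np.random.default_rng(5)
        sets = {n: set(rng.integers(0, 50, size=20).tolist()) for n in "ABC"}
        regions = venn3(sets)
        for name in "ABC":
            total = sum(v for k, v in regions.items() if name in k.split("&"))
            assert total == len(sets[name])


def _evidence_row(**kw):
    base = dict(
        orphan=True, expressed=False, robust=False, zero_everywhere=True,
        peptide=False, liberal_any=False, conservative_any=False,
        n_liberal_datasets=0, exon_count=1, max_fpkm=0.0,
    )
    base.update(kw)
    return base


class TestClassify:
    def _classify(self, rows):
        df = pd.DataFrame([_evidence_row(**r) for r in rows],
                          index=[f"g{i}" for i in range(len(rows))])
        return classify(df, RunConfig())

    def test_selection_dominates_missing_expression(self):
        # significant negative selection without any expression: still coding
        out = self._classify([dict(conservative_any=True, liberal_any=True)])
        assert out.iloc[0] == "coding_orphan"

    def test_robust_expression_without_selection_is_ncrna(self):
        out = self._classify(
            [dict(expressed=True, robust=True, zero_everywhere=False,
                  max_fpkm=50.0)]
        )
        assert out.iloc[0] == "ncRNA_candidate"

    def test_silent_unselected_orphan_is_artifact(self):
        out = self._classify([dict()])
        assert out.iloc[0] == "artifact_or_pseudogene"

    def test_peptide_evidence_is_coding(self):
        out = self._classify([dict(peptide=True)])
        assert out.iloc[0] == "coding_orphan"

    def test_conserved_gene_class(self):
        out = self._classify([dict(orphan=False)])
        assert out.iloc[0] == "conserved"

    def test_weak_expression_unassigned(self):
        out = self._classify(
            [dict(expressed=True, zero_everywhere=False, max_fpkm=3.0)]
        )
        assert out.iloc[0] == "unassigned"

    def test_classes_partition(self):
        rng = np.random.default_rng(1)
        rows = [
            dict(
                orphan=bool(rng.integers(2)),
                expressed=bool(rng.integers(2)),
                robust=bool(rng.integers(2)),
                zero_everywhere=bool(rng.integers(2)),
                peptide=bool(rng.integers(2)),
                liberal_any=bool(rng.integers(2)),
                conservative_any=bool(rng.integers(2)),
            )
            for _ in range(200)
        ]
        out = self._classify(rows)
        assert out.notna().all()
        assert len(out) == 200


class TestCandidates:
    def _frame(self, **kw):
        row = _evidence_row(
            conservative_any=True, zero_everywhere=True,
            n_liberal_datasets=2, exon_count=3,
        )
        row.update(kw)
        return pd.DataFrame([row], index=["g1"])

    def test_meets_all_criteria(self):
        assert select_validation_candidates(self._frame()) == ["g1"]

    def test_two_exons_rejected(self):
        assert select_validation_candidates(self._frame(exon_count=2)) == []

    def test_any_expression_rejected(self):
        assert select_validation_candidates(
            self._frame(zero_everywhere=False, max_fpkm=0.3)
        ) == []

    def test_single_dataset_rejected(self):
        assert select_validation_candidates(
            self._frame(n_liberal_datasets=1)
        ) == []

    def test_removing_a_dataset_never_adds_candidates(self):
        with_two = select_validation_candidates(self._frame())
        with_one = select_validation_candidates(
            self._frame(n_liberal_datasets=1)
        )
        assert set(with_one) <= set(with_two)


class TestFeatureStats:
    def test_exact_rank_sum_example(self):
        # all three ranks of x below all of y: p = 2/20 = 0.1 exactly
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        p = rank_sum_test([1.0, 2.0, 3.5, 7.0], [1.5, 2.5, 4.0, 6.0])
        assert p > 0.5

    def test_feature_table(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "gene_class": ["conserved"] * 30 + ["coding_orphan"] * 30,
                "transcript_length": np.concatenate(
                    [rng.normal(900, 100, 30), rng.normal(300, 60, 30)]
                ),
                "exon_count": rng.integers(1, 9, 60),
                "gc_fraction": rng.uniform(0.3, 0.6, 60),
                "contig_percentile": rng.uniform(0, 100, 60),
            }
        )
        stats = feature_stats(df)
        row = stats[
            (stats["feature"] == "transcript_length")
        ].iloc[0]
        assert row["p_value"] < 0.001


class TestContigPercentile:
    lengths = {f"c{i}": 1000 - i for i in range(100)}

    def test_largest_contig(self):
        genes = pd.Series({"g1": "c0"})
        assert contig_percentile(self.lengths, genes)["g1"] == pytest.approx(1.0)

    def test_smallest_contig(self):
        genes = pd.Series({"g1": "c99"})
        assert contig_percentile(self.lengths, genes)["g1"] == pytest.approx(100.0)

    def test_ties_share_minimum_rank(self):
        lengths = {"a": 10, "b": 10, "c": 5}
        genes = pd.Series({"g1": "a", "g2": "b", "g3": "c"})
        out = contig_percentile(lengths, genes)
        assert out["g1"] == out["g2"] == pytest.approx(100.0 / 3)
        assert out["g3"] == pytest.approx(100.0)

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError):
            contig_percentile(self.lengths, pd.Series({"g1": "nope"}))


class TestOmegaCurve:
    def test_extremes(self):
        omegas = [0.2, 0.5, 0.9]
        curve = omega_cumulative_curve(omegas, thresholds=np.array([0.0, 1.0]))
        assert curve["proportion"].iloc[0] == 0.0
        assert curve["proportion"].iloc[-1] == 1.0

    def test_gc_fraction_of_known_sequence(self):
        from orphanscan.records import GeneModel

        gene = GeneModel("g", "c", "+", [(0, 4)], "ATGC", "?")
        assert gene.gc_fraction == pytest.approx(0.5)
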