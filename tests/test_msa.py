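"""Progressive alignment, back-translation, the 150-nt filter, variant
implantation."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from orphanscan.msa import (
    GAP_EXTEND,
    GAP_OPEN,
    AlignmentError,
    BacktranslationError,
    CodonAlignment,
    backtranslate,
    filter_min_length,
    implant_snvs,
    progressive_align,
    variants_to_cds_coords,
)
from orphanscan.records import GeneModel


def _score_alignment(rows):
    """Sum-of-pairs BLOSUM62 score with affine gaps (first char GAP_OPEN)."""
    b62 = substitution_matrices.load("BLOSUM62")
    a, b = rows
    score = 0.0
    in_gap = False
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            score -= GAP_EXTEND if in_gap else GAP_OPEN
            in_gap = True
        else:
            score += b62[x, y]
            in_gap = False
    return score


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        msa = progressive_align([("a", "MKTAYI"), ("b", "MKTAYI"),
                                 ("c", "MKTAYI")])
        assert all(row == "MKTAYI" for _, row in msa)

    def test_pair_matches_biopython_global_score(self):
        # independent oracle: Biopython's global aligner under the same
        # scoring (BLOSUM62, open 10, extend 0.5)
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -GAP_OPEN
        aligner.extend_gap_score = -GAP_EXTEND
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            s1 = "".join(rng.choice(list(aa), size=rng.integers(5, 30)))
            s2 = "".join(rng.choice(list(aa), size=rng.integers(5, 30)))
            msa = progressive_align([("a", s1), ("b", s2)])
            ours = _score_alignment([row for _, row in msa])
            assert ours == pytest.approx(float(aligner.score(s1, s2)))

    def test_residue_order_preserved(self):
        msa = progressive_align(
            [("a", "MKTAYIAKQRQISFVKSH"), ("b", "MKTIAKQRQISF"),
             ("c", "MKTAYIAKQISFVK")]
        )
        for (name, row), original in zip(
            msa, ["MKTAYIAKQRQISFVKSH", "MKTIAKQRQISF", "MKTAYIAKQISFVK"]
        ):
            assert row.replace("-", "") == original

    def test_prefix_padded_with_trailing_gaps(self):
        msa = progressive_align(
            [("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR"), ("c", "MKTAYI")]
        )
        rows = dict(msa)
        assert rows["c"] == "MKTAYI----"

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            progressive_align([("a", ""), ("b", "MK")])

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            progressive_align([("a", "MK")])


class TestBacktranslate:
    def test_gap_free_pair(self):
        msa = [("a", "MKPF"), ("b", "MKPF")]
        cds = {"a": "ATGAAACCCTTT", "b": "ATGAAGCCGTTC"}
        aln = backtranslate(msa, cds)
        assert aln.n_columns == 12
        assert aln.rows[0] == "ATGAAACCCTTT"

    def test_gap_mapping(self):
        msa = [("a", "M-K"), ("b", "MQK")]
        cds = {"a": "ATGAAA", "b": "ATGCAAAAA"}
        aln = backtranslate(msa, cds)
        assert aln.rows[0] == "ATG---AAA"
        assert aln.rows[1] == "ATGCAAAAA"

    def test_terminal_stop_stripped(self):
        msa = [("a", "MK"), ("b", "MK")]
        cds = {"a": "ATGAAATAA", "b": "ATGAAA"}
        aln = backtranslate(msa, cds)
        assert aln.rows[0] == "ATGAAA"

    def test_internal_stop_rejected(self):
        msa = [("a", "M*K"), ("b", "MQK")]
        cds = {"a": "ATGTAAAAA", "b": "ATGCAAAAA"}
        with pytest.raises(BacktranslationError, match="stop|residue|match"):
            backtranslate(msa, cds)

    def test_length_mismatch_rejected(self):
        msa = [("a", "MK"), ("b", "MK")]
        cds = {"a": "ATGAAAG", "b": "ATGAAA"}
        with pytest.raises(BacktranslationError, match="length"):
            backtranslate(msa, cds)

    def test_translation_mismatch_rejected(self):
        msa = [("a", "MM"), ("b", "MM")]
        cds = {"a": "ATGAAA", "b": "ATGATG"}
        with pytest.raises(BacktranslationError, match="match"):
            backtranslate(msa, cds)

    def test_ungap_round_trip(self):
        msa = [("a", "MK-F"), ("b", "MKQF")]
        cds = {"a": "ATGAAATTT", "b": "ATGAAGCAATTC"}
        aln = backtranslate(msa, cds)
        assert aln.ungapped(0) == "ATGAAATTT"
        assert aln.ungapped(1) == "ATGAAGCAATTC"


class TestLengthFilter:
    def test_boundary_kept(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATG" * 50] * 2)
        assert aln.n_columns == 150
        assert filter_min_length(aln, 150) is True

    def test_one_below_dropped(self):
        # 49 codons + nothing = 147nt; use 149 via gaps is impossible, so
        # check 147 < 150
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATG" * 49] * 2)
        assert filter_min_length(aln, 150) is False

    def test_gap_columns_count(self):
        # gaps are part of the pal2nal-style alignment length
        rows = ["ATG" * 49 + "---", "ATG" * 50]
        aln = CodonAlignment(["a", "b"], rows)
        assert aln.n_columns == 150
        assert filter_min_length(aln, 150) is True

    def test_conservation_of_drops(self, small_dataset):
        # the number of dropped clusters equals the number of short ones
        from orphanscan.clustering import build_clade_pairs

        ds = small_dataset
        pairs = build_clade_pairs(ds.genes, ds.variants_a1, ds.variants_a2)
        short = [g for g, a in pairs.items() if a.n_columns < 150]
        kept = [g for g, a in pairs.items() if filter_min_length(a)]
        assert len(kept) + len(short) == len(pairs)


class TestImplantVariants:
    def test_empty_variant_list_identity(self):
        assert implant_snvs("ATGAAA", []) == "ATGAAA"

    def test_single_snv_hamming_one(self):
        out = implant_snvs("ATGAAA", [(3, "A", "G")])
        assert out == "ATGGAA"
        assert sum(a != b for a, b in zip(out, "ATGAAA")) == 1

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            implant_snvs("ATGAAA", [(3, "C", "G")])

    def test_overlapping_variants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            implant_snvs("ATGAAA", [(3, "A", "G"), (3, "A", "C")])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            implant_snvs("ATGAAA", [(6, "A", "G")])

    def test_minus_strand_alleles_complemented(self):
        # gene on minus strand: contig TTTCAT (exon 2-8 0-based) -> CDS ATGAAA
        gene = GeneModel(
            gene_id="g1", contig="c1", strand="-", exons=[(2, 8)],
            cds="ATGAAA", protein="MK",
        )
        # contig variant at 1-based pos 4 (contig base T, 0-based offset 1 in
        # the spliced forward sequence TTTCAT) -> CDS index 6-1-1 = 4,
        # CDS base A, complemented alleles
        snvs = variants_to_cds_coords(gene, [(4, "T", "C")])
        assert snvs == [(4, "A", "G")]
        assert implant_snvs(gene.cds, snvs) == "ATGAGA"

    def test_variant_outside_exons_ignored(self):
        gene = GeneModel(
            gene_id="g1", contig="c1", strand="+", exons=[(2, 8)],
            cds="ATGAAA", protein="MK",
        )
        assert variants_to_cds_coords(gene, [(1, "A", "G")]) == []
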