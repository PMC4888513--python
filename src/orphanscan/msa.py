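"""Protein multiple alignment, codon back-translation, and allele building.

Cluster proteins are aligned progressively (UPGMA guide tree on 3-mer cosine
distances, profile-profile steps by affine-gap dynamic programming with
BLOSUM62); the protein alignment is then back-translated onto each member's
CDS so that one residue column corresponds to one codon triplet column.  An
alignment shorter than 150 nt (columns, gap columns included) is discarded
from the selection analysis, mirroring the short/poor-alignment filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from . import gencode
from .records import GeneModel

GAP_OPEN = 10.0  # cost of the first gap character
GAP_EXTEND = 0.5  # cost of each further gap character

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_NEG = -1e30

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _blosum62_20() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            out[i, j] = m[a, b]
    return out


_B62 = _blosum62_20()


class AlignmentError(ValueError):
    pass


class BacktranslationError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Gap-aware aligned codon sequences for one cluster."""

    ids: list[str]
    rows: list[str]  # aligned nucleotide strings over {ACGT, '-'}

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows have unequal lengths")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @classmethod
    def from_ungapped(cls, ids: list[str], seqs: list[str]) -> "CodonAlignment":
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("ungapped sequences of unequal length")
        return cls(list(ids), [s.upper() for s in seqs])

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        """Alignment length in nucleotides (gap columns included)."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codon_columns(self) -> int:
        return self.n_columns // 3

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def codes(self) -> np.ndarray:
        """(n_seq, n_codon_columns) sense-codon index matrix, -1 for gaps."""
        return np.vstack([gencode.encode_codons(r) for r in self.rows])


# ---------------------------------------------------------------------------
# progressive protein alignment
# ---------------------------------------------------------------------------


def _profile_counts(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, 20))
    for row in rows:
        for p, ch in enumerate(row):
            k = _AA_INDEX.get(ch)
            if k is not None:
                counts[p, k] += 1
    return counts


def _align_profiles(
    a_rows: list[str], b_rows: list[str]
) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    Column score is the mean BLOSUM62 score over residue pairs; the DP rows
    are vectorized, the horizontal gap state via a running-max scan.
    """
    ca = _profile_counts(a_rows)
    cb = _profile_counts(b_rows)
    n, m = len(ca), len(cb)
    S = (ca @ _B62 @ cb.T) / (len(a_rows) * len(b_rows))

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in A (consume B column)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in B (consume A column)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Ix[0, 1:] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    i = np.arange(1, n + 1)
    Iy[1:, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)

    ext_ramp = GAP_EXTEND * np.arange(m + 1)
    for r in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[r - 1], Ix[r - 1]), Iy[r - 1])
        M[r, 1:] = S[r - 1, :] + best_prev[:-1]
        Iy[r, 1:] = np.maximum(M[r - 1, 1:] - GAP_OPEN, Iy[r - 1, 1:] - GAP_EXTEND)
        A = np.maximum.accumulate(M[r] + ext_ramp)
        Ix[r, 1:] = A[:-1] - GAP_OPEN - GAP_EXTEND * (j - 1)

    # traceback (tie priority M > Ix > Iy keeps it deterministic)
    tables = {"M": M, "Ix": Ix, "Iy": Iy}
    ops: list[str] = []
    r, c = n, m
    state = max(tables, key=lambda s: tables[s][r, c])
    while r > 0 or c > 0:
        if state == "M":
            ops.append("D")
            r, c = r - 1, c - 1
            if r == 0 and c == 0:
                break
            state = max(tables, key=lambda s: tables[s][r, c])
        elif state == "Ix":
            ops.append("B")
            state = (
                "M"
                if M[r, c - 1] - GAP_OPEN >= Ix[r, c - 1] - GAP_EXTEND
                else "Ix"
            )
            c -= 1
        else:  # Iy
            ops.append("A")
            state = (
                "M"
                if M[r - 1, c] - GAP_OPEN >= Iy[r - 1, c] - GAP_EXTEND
                else "Iy"
            )
            r -= 1
    ops.reverse()

    out_a = ["" for _ in a_rows]
    out_b = ["" for _ in b_rows]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, row in enumerate(a_rows):
                out_a[k] += row[ia]
            for k, row in enumerate(b_rows):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif op == "B":  # B column against gaps in A
            for k in range(len(a_rows)):
                out_a[k] += "-"
            for k, row in enumerate(b_rows):
                out_b[k] += row[ib]
            ib += 1
        else:  # A column against gaps in B
            for k, row in enumerate(a_rows):
                out_a[k] += row[ia]
            for k in range(len(b_rows)):
                out_b[k] += "-"
            ia += 1
    if ia != len(a_rows[0]) or ib != len(b_rows[0]):  # pragma: no cover
        raise AlignmentError("traceback failed to consume both profiles")
    return out_a, out_b


def _kmer_vectors(seqs: list[str], k: int = 3) -> np.ndarray:
    vocab: dict[str, int] = {}
    rows = []
    for s in seqs:
        rows.append([s[i : i + k] for i in range(max(len(s) - k + 1, 0))])
        for km in rows[-1]:
            vocab.setdefault(km, len(vocab))
    out = np.zeros((len(seqs), max(len(vocab), 1)))
    for r, kms in enumerate(rows):
        for km in kms:
            out[r, vocab[km]] += 1
    return out


def progressive_align(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Progressive multiple alignment of protein sequences.

    Returns (id, aligned sequence) pairs in the input order.  Requires at
    least two sequences; empty sequences are rejected.
    """
    if len(seqs) < 2:
        raise AlignmentError("need at least 2 sequences to align")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids")
    raw = []
    for i, s in seqs:
        s = s.upper()
        if not s:
            raise AlignmentError(f"empty sequence {i!r}")
        bad = set(s) - set(_AA)
        if bad:
            raise AlignmentError(f"unknown residue(s) {sorted(bad)} in {i!r}")
        raw.append(s)

    if len(seqs) == 2:
        a, b = _align_profiles([raw[0]], [raw[1]])
        merged = {ids[0]: a[0], ids[1]: b[0]}
        return [(i, merged[i]) for i in ids]

    vecs = _kmer_vectors(raw)
    with np.errstate(invalid="ignore"):
        dists = pdist(vecs, metric="cosine")
    dists = np.nan_to_num(dists, nan=1.0)
    Z = linkage(dists, method="average")

    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [raw[i]]) for i in range(len(seqs))
    }
    nxt = len(seqs)
    for za, zb, _, _ in Z:
        pa_ids, pa_rows = profiles.pop(int(za))
        pb_ids, pb_rows = profiles.pop(int(zb))
        new_a, new_b = _align_profiles(pa_rows, pb_rows)
        profiles[nxt] = (pa_ids + pb_ids, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = profiles.values()
    merged = dict(zip(final_ids, final_rows))
    return [(i, merged[i]) for i in ids]


# ---------------------------------------------------------------------------
# back-translation and length filter
# ---------------------------------------------------------------------------


def strip_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 == 0 and cds[-3:] in gencode.STOP_CODONS:
        return cds[:-3]
    return cds


def backtranslate(
    protein_msa: list[tuple[str, str]], cds_by_id: dict[str, str]
) -> CodonAlignment:
    """Convert a protein MSA into the corresponding codon alignment.

    Each residue column becomes a codon triplet column; a protein gap becomes
    ``---``.  The CDS must translate exactly to the ungapped protein row;
    internal stop codons or length mismatches reject the cluster.
    """
    ids, rows = [], []
    for pid, prow in protein_msa:
        cds = strip_terminal_stop(cds_by_id[pid])
        ungapped = prow.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise BacktranslationError(
                f"{pid}: CDS length {len(cds)} != 3 x {len(ungapped)} residues"
            )
        if len(cds) % 3 != 0:
            raise BacktranslationError(f"{pid}: CDS length not divisible by 3")
        codons = gencode.codons_of(cds)
        for k, codon in enumerate(codons):
            if codon in gencode.STOP_CODONS:
                raise BacktranslationError(f"{pid}: internal stop codon at codon {k}")
        translated = gencode.translate_cds(cds)
        if translated != ungapped:
            raise BacktranslationError(
                f"{pid}: CDS translation does not match the aligned protein"
            )
        out = []
        k = 0
        for ch in prow:
            if ch == "-":
                out.append(gencode.GAP_CODON)
            else:
                out.append(codons[k])
                k += 1
        ids.append(pid)
        rows.append("".join(out))
    return CodonAlignment(ids, rows)


def filter_min_length(aln: CodonAlignment, min_nt: int = 150) -> bool:
    """Keep the alignment iff its column count (nt) reaches ``min_nt``."""
    return aln.n_columns >= min_nt


# ---------------------------------------------------------------------------
# lineage alleles (fixed-difference implantation)
# ---------------------------------------------------------------------------


def implant_snvs(cds: str, snvs: list[tuple[int, str, str]]) -> str:
    """Apply (0-based CDS position, ref, alt) substitutions to a CDS."""
    seq = list(cds.upper())
    seen: set[int] = set()
    for pos, ref, alt in snvs:
        if not (0 <= pos < len(seq)):
            raise ValueError(f"variant position {pos} outside CDS of length {len(seq)}")
        if pos in seen:
            raise ValueError(f"overlapping variants at CDS position {pos}")
        seen.add(pos)
        if seq[pos] != ref.upper():
            raise ValueError(
                f"reference mismatch at CDS position {pos}: CDS has {seq[pos]}, "
                f"variant claims {ref}"
            )
        seq[pos] = alt.upper()
    return "".join(seq)


def variants_to_cds_coords(
    gene: GeneModel, variants: list[tuple[int, str, str]]
) -> list[tuple[int, str, str]]:
    """Map contig-coordinate SNVs (1-based pos, ref, alt on the forward
    strand) into CDS coordinates, complementing alleles on minus-strand genes.

    Variants outside the gene's exons are ignored (they do not touch the CDS).
    """
    # forward-strand spliced offsets
    offsets: dict[int, int] = {}
    o = 0
    for start, end in sorted(gene.exons):
        for p in range(start, end):
            offsets[p] = o
            o += 1
    L = o
    out = []
    for pos1, ref, alt in variants:
        p0 = pos1 - 1
        if p0 not in offsets:
            continue
        fwd = offsets[p0]
        if gene.strand == "+":
            out.append((fwd, ref.upper(), alt.upper()))
        else:
            out.append(
                (
                    L - 1 - fwd,
                    ref.upper().translate(_COMPLEMENT),
                    alt.upper().translate(_COMPLEMENT),
                )
            )
    return sorted(out)
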