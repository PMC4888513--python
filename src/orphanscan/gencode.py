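"""Lookup tables for the standard genetic code restricted to the 61 sense codons.

Codon substitution models (and the counting methods used to cross-check them)
operate on the sense codons only; stop codons are excluded from the state
space.  All tables here are derived once, at import, from Biopython's standard
code (NCBI table 1) and indexed by the alphabetically sorted sense codons.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        c
        for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
        if c not in _TABLE.stop_codons
    )
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

GAP_CODON = "---"
GAP_CODE = -1


def is_transition(a: str, b: str) -> bool:
    """True if the a<->b nucleotide change is a transition (A<->G or C<->T)."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def _build_tables():
    n = N_SENSE
    ndiff = np.zeros((n, n), dtype=np.int8)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    nt_hamming = np.zeros((n, n), dtype=np.int8)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            diffs = [p for p in range(3) if a[p] != b[p]]
            ndiff[i, j] = len(diffs)
            nt_hamming[i, j] = len(diffs)
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
            if len(diffs) == 1:
                p = diffs[0]
                single[i, j] = True
                transition[i, j] = is_transition(a[p], b[p])
    return ndiff, single, transition, synonymous, nt_hamming


(
    NT_DIFF_COUNT,
    SINGLE_NT_CHANGE,
    IS_TRANSITION,
    IS_SYNONYMOUS,
    NT_HAMMING,
) = _build_tables()


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3, no internal stops enforced by caller)."""
    return str(Seq(cds).translate())


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def encode_codons(seq: str, allow_gaps: bool = True) -> np.ndarray:
    """Encode an (aligned) nucleotide sequence as sense-codon indices.

    Gap codons ("---") become ``GAP_CODE``.  Codons mixing gap and nucleotide
    characters, stop codons, and codons with ambiguous letters raise.
    """
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k, codon in enumerate(codons_of(seq.upper())):
        if codon == GAP_CODON:
            if not allow_gaps:
                raise ValueError("gap codon in ungapped context")
            out[k] = GAP_CODE
        elif codon in CODON_INDEX:
            out[k] = CODON_INDEX[codon]
        elif codon in _TABLE.stop_codons:
            raise ValueError(f"stop codon {codon} at codon position {k}")
        else:
            raise ValueError(f"unrecognized codon {codon!r} at codon position {k}")
    return out


def decode_codons(codes: np.ndarray) -> str:
    return "".join(
        GAP_CODON if c == GAP_CODE else SENSE_CODONS[c] for c in np.asarray(codes)
    )
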