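"""Shared domain records passed between pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; parsers
convert from the 1-based inclusive conventions of GFF3 and the variant table
exactly once, at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """A predicted protein-coding gene of the focal species."""

    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # 0-based half-open, contig coordinates, sorted
    cds: str  # spliced, strand-corrected coding sequence
    protein: str  # translation of cds (no trailing "*")
    orphan: bool = False
    valid_cds: bool = True  # False when CDS length is not divisible by 3

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return len(self.cds)

    @property
    def gc_fraction(self) -> float:
        if not self.cds:
            return float("nan")
        s = self.cds.upper()
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class ClusterRecord:
    """A homology cluster with species-tagged members and its dataset roles."""

    cluster_id: str
    members: list[tuple[str, str]]  # (species, gene_id)
    ppa_orphan: int = 0
    ppa_conserved: int = 0
    pex: int = 0
    category: str = ""  # orphan | conserved | hybrid | pex_specific
    in_ortholog: bool = False
    in_paralog: bool = False

    @property
    def ppa_members(self) -> list[str]:
        return [g for sp, g in self.members if sp == "ppa"]

    @property
    def pex_members(self) -> list[str]:
        return [g for sp, g in self.members if sp == "pex"]


@dataclass
class PeptideHit:
    peptide_id: str
    peptide: str
    protein_id: str
    start: int  # 0-based offset into the protein

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass
class RunConfig:
    """Thresholds and knobs of the classification pipeline.

    Defaults are the published analysis values: FPKM >= 1 marks expression and
    FPKM >= 10 robust expression; omega < 0.6 is the liberal negative-selection
    cutoff; the conservative call requires omega < 1 with a BH-adjusted LRT
    p-value below alpha = 0.05; codon alignments shorter than 150 nt are
    dropped; PCR-validation candidates need more than 2 exons and a liberal
    omega call in at least 2 of the 3 datasets.
    """

    fpkm_expressed: float = 1.0
    fpkm_robust: float = 10.0
    omega_liberal: float = 0.6
    alpha: float = 0.05
    min_alignment_nt: int = 150
    min_candidate_exons: int = 3
    min_candidate_datasets: int = 2
    edge_threshold: float = 0.3
    mcl_inflation: float = 2.0
    n_permutations: int = 10
    ncrna_rule: str = "liberal"  # which selection rule defines "no strong selection"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("fpkm_expressed", "fpkm_robust", "omega_liberal",
                     "min_alignment_nt", "edge_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ncrna_rule not in ("liberal", "conservative"):
            raise ValueError("ncrna_rule must be 'liberal' or 'conservative'")


DATASETS = ("ortholog", "paralog", "cladeAB")

GENE_CLASSES = (
    "artifact_or_pseudogene",
    "ncRNA_candidate",
    "coding_orphan",
    "conserved",
    "unassigned",
)
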