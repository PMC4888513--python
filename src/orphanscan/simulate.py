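"""Synthetic study generator with known ground truth.

The generator emulates the study design the pipeline was built for: a focal
nematode genome with predicted orphan and conserved genes, a sister species
at roughly 10 % nucleotide divergence, two intra-species lineages around 1 %
apart, 14 RNA-seq samples, differential-expression gene sets, and a peptide
catalog biased toward conserved genes.  Every gene carries a hidden true
class and every homology cluster a true omega, so each downstream stage can
be scored against truth.

Sequences evolve under the GY94 M0 model restricted to the 61 sense codons
(no indels, no stop codons); requested divergences are *nucleotide*
divergences, converted internally to codon branch lengths by inverting the
model's expected-divergence curve.  Orphan genes are drawn shorter and with
fewer exons than conserved genes, echoing the feature contrasts the
classification is meant to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gencode, io as oio
from .codonmodel import M0SubstitutionModel
from .msa import CodonAlignment
from .records import GeneModel
from .trees import PhyloTree, simulate_tree  # noqa: F401  (re-exported)

GENE_CLASSES = ("conserved", "orphan_coding", "orphan_ncrna", "orphan_artifact")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Divergences are expected nucleotide divergences (0.10 between the two
    species, 0.01 between the intra-species clades).  Omega laws, lengths,
    exon counts, expression and peptide coverage are per gene class;
    ``orphan_coding`` genes evolve under clear negative selection,
    ``orphan_ncrna`` and ``orphan_artifact`` genes neutrally (their open
    reading frames are not protein-coding), and ncRNA candidates are robustly
    expressed while artifacts are never expressed.
    """

    n_conserved: int = 300
    n_orphan: int = 200
    orphan_fractions: dict = field(
        default_factory=lambda: {"coding": 0.6, "ncrna": 0.2, "artifact": 0.2}
    )
    omega_law: dict = field(
        default_factory=lambda: {
            "conserved": ("lognormal", np.log(0.15), 0.4),
            "orphan_coding": ("lognormal", np.log(0.25), 0.4),
            "orphan_ncrna": ("fixed", 1.0),
            "orphan_artifact": ("fixed", 1.0),
        }
    )
    kappa: float = 2.0
    codon_length_law: dict = field(
        default_factory=lambda: {
            "conserved": (350, 0.45),  # (median codons, lognormal sigma)
            "orphan_coding": (150, 0.45),
            "orphan_ncrna": (130, 0.45),
            "orphan_artifact": (130, 0.45),
        }
    )
    min_codons: int = 50
    exon_mean: dict = field(
        default_factory=lambda: {
            "conserved": 6.0,
            "orphan_coding": 3.0,
            "orphan_ncrna": 2.5,
            "orphan_artifact": 2.5,
        }
    )
    interspecies_divergence: float = 0.10
    intraclade_divergence: float = 0.01
    paralog_fraction: float = 0.12
    n_samples: int = 14
    expressed_fraction: dict = field(
        default_factory=lambda: {
            "conserved": 0.90,
            "orphan_coding": 0.55,
            "orphan_ncrna": 1.0,
            "orphan_artifact": 0.0,
        }
    )
    fpkm_log_mean: dict = field(
        default_factory=lambda: {
            "conserved": 1.5,
            "orphan_coding": 1.0,
            "orphan_ncrna": 3.0,
            "orphan_artifact": 0.0,
        }
    )
    fpkm_log_sigma: float = 1.5
    peptide_coverage: dict = field(
        default_factory=lambda: {
            "conserved": 0.25,
            "orphan_coding": 0.07,
            "orphan_ncrna": 0.0,
            "orphan_artifact": 0.0,
        }
    )
    peptide_length: tuple = (7, 25)
    max_peptides_per_gene: int = 3
    n_decoy_peptides: int = 20
    n_de_sets: int = 6
    de_rate_conserved: float = 0.15
    de_rate_orphan: float = 0.075
    n_contigs: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_conserved < 0 or self.n_orphan < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_conserved + self.n_orphan == 0:
            raise ValueError("need at least one gene")
        if abs(sum(self.orphan_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("orphan_fractions must sum to 1")
        for d in (self.expressed_fraction, self.peptide_coverage):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fraction {k}={v} outside [0, 1]")
        if not 0.0 < self.interspecies_divergence < 0.6:
            raise ValueError("interspecies_divergence out of range")
        if not 0.0 < self.intraclade_divergence < 0.6:
            raise ValueError("intraclade_divergence out of range")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.min_codons < 1:
            raise ValueError("min_codons must be >= 1")
        if self.n_samples < 1:
            raise ValueError("need at least one RNA-seq sample")
        if self.n_contigs < 1:
            raise ValueError("need at least one contig")


@dataclass
class SyntheticTruth:
    """Hidden ground truth: per gene its class/cluster/omega, per cluster
    the generating tree and omega."""

    genes: dict  # gene_id -> {"gene_class", "cluster_id", "omega"}
    clusters: dict  # cluster_id -> {"tree", "omega", "members"}

    def to_json(self) -> str:
        return json.dumps(
            {"genes": self.genes, "clusters": self.clusters},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(genes=d["genes"], clusters=d["clusters"])


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def _evolve(codes: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(codes)
    for s in np.unique(codes):
        idx = np.nonzero(codes == s)[0]
        out[idx] = rng.choice(gencode.N_SENSE, size=idx.size, p=P[s])
    return out


def simulate_codon_msa(
    tree: PhyloTree | str,
    omega: float,
    kappa: float,
    freqs: np.ndarray,
    n_codons: int,
    seed: int,
) -> CodonAlignment:
    """Evolve an ungapped codon alignment down a tree under the M0 model.

    The root sequence is drawn from ``freqs``; each child is evolved from its
    parent through exp(Q t) for the edge length t.  Output rows never contain
    stop codons (the model's state space is the 61 sense codons) and are
    byte-identical for identical seeds.
    """
    if isinstance(tree, str):
        tree = PhyloTree.from_newick(tree)
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    model = M0SubstitutionModel(omega, kappa, np.asarray(freqs, float))
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    # root-first traversal: iterate postorder list in reverse
    for node in range(tree.n_nodes - 1, -1, -1):
        if node == tree.root:
            seqs[node] = rng.choice(gencode.N_SENSE, size=n_codons, p=model.pi)
        for child in tree.children[node]:
            t = tree.edge_length[child]
            if t == 0.0:
                seqs[child] = seqs[node].copy()
            else:
                seqs[child] = _evolve(seqs[node], model.transition_matrix(t), rng)
    ids, rows = [], []
    for leaf in tree.leaves:
        ids.append(tree.labels[leaf])
        rows.append(gencode.decode_codons(seqs[leaf]))
    return CodonAlignment(ids, rows)


def _draw_pi(rng: np.random.Generator) -> np.ndarray:
    """Per-gene codon frequencies: Dirichlet positional nucleotide biases
    multiplied into sense-codon frequencies (an F3x4-compatible law)."""
    pos = [rng.dirichlet(np.full(4, 10.0)) for _ in range(3)]
    nt_index = {c: k for k, c in enumerate(gencode.NUCLEOTIDES)}
    pi = np.array(
        [
            pos[0][nt_index[c[0]]] * pos[1][nt_index[c[1]]] * pos[2][nt_index[c[2]]]
            for c in gencode.SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _draw(law: tuple, rng: np.random.Generator) -> float:
    kind = law[0]
    if kind == "fixed":
        return float(law[1])
    if kind == "lognormal":
        return float(rng.lognormal(law[1], law[2]))
    if kind == "uniform":
        return float(rng.uniform(law[1], law[2]))
    raise ValueError(f"unknown law {kind!r}")


# ---------------------------------------------------------------------------
# the dataset object
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """All pipeline inputs, in memory, plus the hidden truth."""

    config: SimulationConfig
    contigs: dict[str, str]
    genes: dict[str, GeneModel]  # focal species, paralog copies included
    pex_cds: dict[str, str]
    pex_proteins: dict[str, str]
    labels: dict[str, bool]
    fpkm: pd.DataFrame
    de_sets: list[set]
    peptides: dict[str, str]
    variants_a1: pd.DataFrame
    variants_a2: pd.DataFrame
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        oio.write_fasta(self.contigs, out / "contigs.fa")
        oio.write_gff3(self.genes, out / "genes.gff3")
        oio.write_fasta({g: m.cds for g, m in self.genes.items()}, out / "ppa_cds.fa")
        oio.write_fasta(
            {g: m.protein for g, m in self.genes.items()}, out / "ppa_protein.fa"
        )
        oio.write_fasta(self.pex_cds, out / "pex_cds.fa")
        oio.write_fasta(self.pex_proteins, out / "pex_protein.fa")
        oio.write_labels(self.labels, out / "labels.tsv")
        oio.write_fpkm(self.fpkm, out / "fpkm.tsv")
        oio.write_de_sets(self.de_sets, out / "de_sets.tsv")
        oio.write_fasta(self.peptides, out / "peptides.fa")
        oio.write_variant_table(self.variants_a1, out / "variants_a1.tsv")
        oio.write_variant_table(self.variants_a2, out / "variants_a2.tsv")
        with oio.atomic_write(out / "truth.json") as fh:
            fh.write(self.truth.to_json())
            fh.write("\n")


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full synthetic study (optionally writing it to disk).

    Identical configs produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # class assignment, shuffled so contigs mix classes
    classes = ["conserved"] * config.n_conserved
    n_orph = config.n_orphan
    counts = {
        k: int(round(v * n_orph)) for k, v in sorted(config.orphan_fractions.items())
    }
    drift = n_orph - sum(counts.values())
    if counts:
        first = sorted(counts)[0]
        counts[first] += drift
    for name, cnt in sorted(counts.items()):
        classes.extend([f"orphan_{name}"] * cnt)
    classes = [classes[i] for i in rng.permutation(len(classes))]

    genes: dict[str, GeneModel] = {}
    labels: dict[str, bool] = {}
    pex_cds: dict[str, str] = {}
    pex_proteins: dict[str, str] = {}
    truth_genes: dict[str, dict] = {}
    truth_clusters: dict[str, dict] = {}
    gene_class: dict[str, str] = {}
    gene_cds: dict[str, str] = {}
    clade_alleles: dict[str, tuple[str, str]] = {}

    child_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    for i, gclass in enumerate(classes):
        gid = f"g{i + 1:05d}"
        xid = f"x{i + 1:05d}"
        cid = f"truth{i + 1:05d}"
        pi = _draw_pi(rng)
        omega = min(max(_draw(config.omega_law[gclass], rng), 1e-3), 9.0)
        median, sigma = config.codon_length_law[gclass]
        n_codons = max(config.min_codons, int(round(rng.lognormal(np.log(median), sigma))))
        model = M0SubstitutionModel(omega, config.kappa, pi)
        t_inter = model.path_length_for_nt_divergence(config.interspecies_divergence)
        t_intra = model.path_length_for_nt_divergence(config.intraclade_divergence)

        has_paralog = gclass in ("conserved", "orphan_coding") and (
            rng.random() < config.paralog_fraction
        )
        if has_paralog:
            pid = f"{gid}p"
            # speciation at the root; duplication halfway down the focal branch
            h = t_inter / 2.0
            tree = PhyloTree.from_newick(
                f"(({gid}:{h / 2:.10g},{pid}:{h / 2:.10g}):{h / 2:.10g},"
                f"{xid}:{h:.10g});"
            )
        else:
            pid = None
            tree = PhyloTree.pair(gid, xid, t_inter)
        aln = simulate_codon_msa(
            tree, omega, config.kappa, pi, n_codons, child_seed()
        )
        seq_of = dict(zip(aln.ids, aln.rows))
        members = [gid] + ([pid] if pid else []) + [xid]
        truth_clusters[cid] = {
            "tree": tree.to_newick(),
            "omega": omega,
            "members": members,
        }
        pex_cds[xid] = seq_of[xid]
        pex_proteins[xid] = gencode.translate_cds(seq_of[xid])

        for g in [gid] + ([pid] if pid else []):
            gene_cds[g] = seq_of[g]
            gene_class[g] = gclass
            labels[g] = gclass != "conserved"
            truth_genes[g] = {
                "gene_class": gclass,
                "cluster_id": cid,
                "omega": omega,
            }
            # intra-species lineage alleles: each clade evolved independently
            # from the reference CDS at the same omega, so the A1-A2 path
            # length is t_intra
            half = model.transition_matrix(t_intra / 2.0)
            ref_codes = gencode.encode_codons(gene_cds[g])
            a1 = gencode.decode_codons(_evolve(ref_codes, half, rng))
            a2 = gencode.decode_codons(_evolve(ref_codes, half, rng))
            clade_alleles[g] = (a1, a2)

    gene_ids = sorted(gene_cds)

    # -- genome layout ------------------------------------------------------
    contig_names = [f"contig{k + 1:03d}" for k in range(config.n_contigs)]
    weights = np.sort(rng.lognormal(0.0, 1.0, size=config.n_contigs))[::-1]
    assignment = rng.choice(
        config.n_contigs, size=len(gene_ids), p=weights / weights.sum()
    )
    contig_parts: dict[str, list[str]] = {c: [] for c in contig_names}
    contig_pos: dict[str, int] = {c: 0 for c in contig_names}

    def random_nt(n: int) -> str:
        return "".join(
            gencode.NUCLEOTIDES[k] for k in rng.integers(0, 4, size=n)
        )

    for g, ci in zip(gene_ids, assignment):
        contig = contig_names[ci]
        cds = gene_cds[g]
        gclass = gene_class[g]
        strand = "+" if rng.random() < 0.5 else "-"
        lam = max(config.exon_mean[gclass] - 1.0, 0.0)
        n_exons = 1 + int(rng.poisson(lam))
        n_exons = min(n_exons, max(len(cds) // 30, 1))
        # split the CDS into n_exons non-empty pieces
        if n_exons > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)
            ).tolist()
        else:
            cuts = []
        bounds = [0] + cuts + [len(cds)]
        pieces = [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        plus_pieces = pieces if strand == "+" else [
            _revcomp(p) for p in reversed(pieces)
        ]
        # leading intergenic spacer
        spacer = int(rng.integers(100, 300))
        contig_parts[contig].append(random_nt(spacer))
        contig_pos[contig] += spacer
        exons = []
        for k, piece in enumerate(plus_pieces):
            if k > 0:
                intron = int(rng.integers(30, 80))
                contig_parts[contig].append(random_nt(intron))
                contig_pos[contig] += intron
            start = contig_pos[contig]
            contig_parts[contig].append(piece)
            contig_pos[contig] += len(piece)
            exons.append((start, contig_pos[contig]))
        genes[g] = GeneModel(
            gene_id=g,
            contig=contig,
            strand=strand,
            exons=exons,
            cds=cds,
            protein=gencode.translate_cds(cds),
            orphan=labels[g],
        )
    for contig in contig_names:
        tail = int(rng.integers(200, 500))
        contig_parts[contig].append(random_nt(tail))
        contig_pos[contig] += tail
    contigs = {c: "".join(contig_parts[c]) for c in contig_names}

    # -- variant tables (fixed differences of each clade vs the reference) --
    def variant_rows(g: str, allele: str) -> list[dict]:
        gene = genes[g]
        L = len(gene.cds)
        fwd_positions: list[int] = []
        for s, e in gene.exons:
            fwd_positions.extend(range(s, e))
        rows = []
        for c, (ref_nt, alt_nt) in enumerate(zip(gene.cds, allele)):
            if ref_nt == alt_nt:
                continue
            o = c if gene.strand == "+" else L - 1 - c
            pos0 = fwd_positions[o]
            if gene.strand == "+":
                rows.append({"contig": gene.contig, "pos": pos0 + 1,
                             "ref": ref_nt, "alt": alt_nt})
            else:
                rows.append(
                    {
                        "contig": gene.contig,
                        "pos": pos0 + 1,
                        "ref": ref_nt.translate(_COMPLEMENT),
                        "alt": alt_nt.translate(_COMPLEMENT),
                    }
                )
        return rows

    rows_a1: list[dict] = []
    rows_a2: list[dict] = []
    for g in gene_ids:
        a1, a2 = clade_alleles[g]
        rows_a1.extend(variant_rows(g, a1))
        rows_a2.extend(variant_rows(g, a2))
    columns = ["contig", "pos", "ref", "alt"]
    variants_a1 = pd.DataFrame(rows_a1, columns=columns).sort_values(
        ["contig", "pos"], kind="stable", ignore_index=True
    )
    variants_a2 = pd.DataFrame(rows_a2, columns=columns).sort_values(
        ["contig", "pos"], kind="stable", ignore_index=True
    )

    # -- expression ---------------------------------------------------------
    samples = [f"sample{k + 1:02d}" for k in range(config.n_samples)]
    fpkm = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    for g in gene_ids:
        gclass = gene_class[g]
        if rng.random() >= config.expressed_fraction[gclass]:
            continue
        n_on = 1 + int(rng.binomial(config.n_samples - 1, 0.5))
        on = rng.choice(config.n_samples, size=n_on, replace=False)
        vals = rng.lognormal(config.fpkm_log_mean[gclass], config.fpkm_log_sigma,
                             size=n_on)
        # guarantee the class's defining stratum exists
        floor = 12.0 if gclass == "orphan_ncrna" else 1.5
        if vals.max() < floor:
            vals = vals * (floor / vals.max())
        fpkm.loc[g, [samples[k] for k in sorted(on)]] = np.round(vals, 3)

    # -- differential-expression gene sets ----------------------------------
    expressed = set(fpkm.index[(fpkm >= 1.0).any(axis=1)])
    de_sets: list[set] = []
    for _ in range(config.n_de_sets):
        chosen = set()
        for g in gene_ids:
            if g not in expressed:
                continue
            rate = (
                config.de_rate_orphan if labels[g] else config.de_rate_conserved
            )
            if rng.random() < rate:
                chosen.add(g)
        de_sets.append(chosen)

    # -- peptides -----------------------------------------------------------
    peptides: dict[str, str] = {}
    k_pep = 0
    for g in gene_ids:
        gclass = gene_class[g]
        if rng.random() >= config.peptide_coverage[gclass]:
            continue
        protein = genes[g].protein
        for _ in range(int(rng.integers(1, config.max_peptides_per_gene + 1))):
            lo, hi = config.peptide_length
            L = int(rng.integers(lo, hi + 1))
            L = min(L, len(protein))
            start = int(rng.integers(0, len(protein) - L + 1))
            k_pep += 1
            peptides[f"pep{k_pep:05d}"] = protein[start : start + L]
    all_proteins = [genes[g].protein for g in gene_ids]
    n_decoys = 0
    attempts = 0
    while n_decoys < config.n_decoy_peptides and attempts < 10 * config.n_decoy_peptides:
        attempts += 1
        g = gene_ids[int(rng.integers(len(gene_ids)))]
        protein = genes[g].protein
        lo, hi = config.peptide_length
        L = min(int(rng.integers(lo, hi + 1)), len(protein))
        start = int(rng.integers(0, len(protein) - L + 1))
        shuffled = "".join(
            np.array(list(protein[start : start + L]))[
                rng.permutation(L)
            ].tolist()
        )
        if any(shuffled in p for p in all_proteins):
            continue
        n_decoys += 1
        peptides[f"decoy{n_decoys:03d}"] = shuffled

    truth = SyntheticTruth(genes=truth_genes, clusters=truth_clusters)
    dataset = SyntheticDataset(
        config=config,
        contigs=contigs,
        genes=genes,
        pex_cds=pex_cds,
        pex_proteins=pex_proteins,
        labels=labels,
        fpkm=fpkm,
        de_sets=de_sets,
        peptides=peptides,
        variants_a1=variants_a1,
        variants_a2=variants_a2,
        truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
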