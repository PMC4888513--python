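"""The study-level model/results pair.

``OrphanGeneStudy`` is built from the pipeline's inputs (gene models of the
focal species, sister-species sequences, FPKM matrix, DE gene sets, peptide
catalog, clade variant tables); ``fit()`` runs homology clustering, codon
alignment, selection inference on the three datasets, expression and peptide
evidence, and the final classification, returning an ``OrphanStudyResult``
that carries every intermediate table, the per-gene evidence frame, summary
counts, and plotting/saving helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evidence as ev
from . import io as oio
from .clustering import (
    build_clade_pairs,
    build_graph,
    categorize_clusters,
    markov_cluster,
)
from .expression import (
    de_membership,
    de_saturation,
    expressed_flags,
    saturation,
)
from .m0 import run_dataset
from .msa import (
    BacktranslationError,
    CodonAlignment,
    backtranslate,
    filter_min_length,
    progressive_align,
    strip_terminal_stop,
)
from .peptides import match_peptides
from .records import DATASETS, ClusterRecord, GeneModel, RunConfig
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class OrphanStudyResult:
    """Everything the classification run produced."""

    config: RunConfig
    evidence: pd.DataFrame  # one row per focal gene
    selection: dict  # dataset -> per-cluster results frame
    clusters: list  # ClusterRecord list
    exclusions: pd.DataFrame
    drops: pd.DataFrame  # clusters removed before selection, with reasons
    saturation: pd.DataFrame
    de_saturation: pd.DataFrame
    peptide_hits: list
    candidates: list
    feature_tests: pd.DataFrame
    summary_dict: dict

    @property
    def class_counts(self) -> dict:
        return self.evidence["gene_class"].value_counts().to_dict()

    @property
    def venn_liberal(self) -> dict:
        return self.summary_dict["venn_liberal"]

    @property
    def venn_conservative(self) -> dict:
        return self.summary_dict["venn_conservative"]

    def omega_curve(self, dataset: str, orphan: bool) -> pd.DataFrame:
        """Cumulative proportion of clusters below each omega threshold."""
        table = self.selection[dataset]
        if table.empty:
            return ev.omega_cumulative_curve([])
        ids = {
            c.cluster_id
            for c in self.clusters
            if (c.category == "orphan") == orphan
        }
        if dataset == "cladeAB":
            orphan_map = self.evidence["orphan"]
            sub = table[table["cluster_id"].map(orphan_map).fillna(False) == orphan]
        else:
            sub = table[table["cluster_id"].isin(ids)]
        return ev.omega_cumulative_curve(sub["omega"].to_numpy())

    def summary(self) -> str:
        s = self.summary_dict
        lines = [
            "Orphan gene classification summary",
            "=" * 50,
            f"genes                      {s['n_genes']}"
            f"  (orphan {s['n_orphan']}, conserved {s['n_conserved']})",
            "",
            "expression (FPKM >= {:g} / >= {:g}):".format(
                s["thresholds"]["fpkm_expressed"], s["thresholds"]["fpkm_robust"]
            ),
            f"  expressed orphans        {s['expressed']['orphan']}",
            f"  robust orphans           {s['robust']['orphan']}",
            f"  zero-everywhere orphans  {s['zero_everywhere_orphan']}",
            f"  peptide-backed orphans   {s['peptide']['orphan']}",
            "",
            "negative selection:",
            f"  liberal (omega < {s['thresholds']['omega_liberal']:g}) orphans"
            f"      {s['negative_selection']['liberal_orphan']}",
            f"  conservative (q < {s['thresholds']['alpha']:g}) orphans"
            f"     {s['negative_selection']['conservative_orphan']}",
            "",
            "datasets:",
        ]
        for ds in DATASETS:
            d = s["datasets"].get(ds, {})
            lines.append(
                f"  {ds:<10} clusters {d.get('n_clusters', 0):>6}"
                f"   significant {d.get('n_significant', 0):>6}"
            )
        lines.extend(["", "gene classes:"])
        for name, count in sorted(s["class_counts"].items()):
            lines.append(f"  {name:<24} {count:>6}")
        lines.append("")
        lines.append(f"validation candidates      {s['n_validation_candidates']}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with oio.atomic_write(out / "evidence.tsv") as fh:
            self.evidence.to_csv(fh, sep="\t", index_label="gene_id")
        for ds, table in self.selection.items():
            with oio.atomic_write(out / f"selection_{ds}.tsv") as fh:
                table.to_csv(fh, sep="\t", index=False)
        oio.write_groups(self.clusters, out / "groups.txt")
        with oio.atomic_write(out / "exclusions.tsv") as fh:
            self.exclusions.to_csv(fh, sep="\t", index=False)
        with oio.atomic_write(out / "alignment_drops.tsv") as fh:
            self.drops.to_csv(fh, sep="\t", index=False)
        with oio.atomic_write(out / "saturation.tsv") as fh:
            self.saturation.to_csv(fh, sep="\t", index=False)
        with oio.atomic_write(out / "de_saturation.tsv") as fh:
            self.de_saturation.to_csv(fh, sep="\t", index=False)
        with oio.atomic_write(out / "peptide_hits.tsv") as fh:
            fh.write("peptide_id\tpeptide\tprotein_id\tstart\tlength\n")
            for h in self.peptide_hits:
                fh.write(
                    f"{h.peptide_id}\t{h.peptide}\t{h.protein_id}\t{h.start}\t"
                    f"{h.length}\n"
                )
        with oio.atomic_write(out / "feature_tests.tsv") as fh:
            self.feature_tests.to_csv(fh, sep="\t", index=False)
        oio.write_json(self.summary_dict, out / "summary.json")

    # plotting lives in .plots; thin forwarding keeps the results object handy
    def plot_saturation(self, ax=None):
        from .plots import plot_saturation

        return plot_saturation(self.saturation, ax=ax)

    def plot_omega_curves(self, dataset: str, ax=None):
        from .plots import plot_omega_curves

        return plot_omega_curves(self, dataset, ax=ax)

    def plot_class_feature(self, feature: str, ax=None):
        from .plots import plot_class_feature

        return plot_class_feature(self.evidence, feature, ax=ax)


class OrphanGeneStudy:
    """The full evidence-integration analysis, as a fittable model.

    Parameters mirror the study's inputs; ``labels`` (gene -> orphan flag)
    defaults to the flags already on the gene models.  ``fit`` executes the
    pipeline and returns an :class:`OrphanStudyResult`.
    """

    def __init__(
        self,
        genes: dict[str, GeneModel],
        pex_cds: dict[str, str],
        pex_proteins: dict[str, str],
        fpkm: pd.DataFrame,
        de_sets: list[set],
        peptides: dict[str, str],
        variants_a1: pd.DataFrame,
        variants_a2: pd.DataFrame,
        contig_lengths: dict[str, int],
        labels: dict[str, bool] | None = None,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.config.validate()
        self.genes = genes
        self.pex_cds = {k: strip_terminal_stop(v) for k, v in pex_cds.items()}
        self.pex_proteins = pex_proteins
        self.fpkm = fpkm
        self.de_sets = de_sets
        self.peptides = peptides
        self.variants_a1 = variants_a1
        self.variants_a2 = variants_a2
        self.contig_lengths = contig_lengths
        if labels is not None:
            for gid, orphan in labels.items():
                if gid in genes:
                    genes[gid].orphan = bool(orphan)
        overlap = set(genes) & set(pex_proteins)
        if overlap:
            raise ValueError(
                f"gene ids shared between species: {sorted(overlap)[:5]}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_simulation(
        cls,
        sim_config: SimulationConfig,
        config: RunConfig | None = None,
    ) -> tuple["OrphanGeneStudy", SyntheticDataset]:
        ds = generate_dataset(sim_config)
        study = cls.from_dataset(ds, config=config)
        return study, ds

    @classmethod
    def from_dataset(
        cls, ds: SyntheticDataset, config: RunConfig | None = None
    ) -> "OrphanGeneStudy":
        return cls(
            genes=ds.genes,
            pex_cds=ds.pex_cds,
            pex_proteins=ds.pex_proteins,
            fpkm=ds.fpkm,
            de_sets=ds.de_sets,
            peptides=ds.peptides,
            variants_a1=ds.variants_a1,
            variants_a2=ds.variants_a2,
            contig_lengths={c: len(s) for c, s in ds.contigs.items()},
            labels=ds.labels,
            config=config,
        )

    @classmethod
    def from_directory(
        cls, path: str | Path, config: RunConfig | None = None
    ) -> "OrphanGeneStudy":
        p = Path(path)
        for name in (
            "contigs.fa",
            "genes.gff3",
            "pex_cds.fa",
            "pex_protein.fa",
            "labels.tsv",
            "fpkm.tsv",
            "de_sets.tsv",
            "peptides.fa",
            "variants_a1.tsv",
            "variants_a2.tsv",
        ):
            if not (p / name).exists():
                raise FileNotFoundError(f"missing input file: {p / name}")
        contigs = oio.read_fasta(p / "contigs.fa")
        labels = oio.read_labels(p / "labels.tsv")
        genes = oio.read_gff3(p / "genes.gff3", contigs, labels)
        return cls(
            genes=genes,
            pex_cds=oio.read_fasta(p / "pex_cds.fa"),
            pex_proteins=oio.read_fasta(p / "pex_protein.fa"),
            fpkm=oio.read_fpkm(p / "fpkm.tsv"),
            de_sets=oio.read_de_sets(p / "de_sets.tsv"),
            peptides=oio.read_fasta(p / "peptides.fa"),
            variants_a1=oio.read_variant_table(p / "variants_a1.tsv"),
            variants_a2=oio.read_variant_table(p / "variants_a2.tsv"),
            contig_lengths={c: len(s) for c, s in contigs.items()},
            labels=labels,
            config=config,
        )

    # -- pipeline -----------------------------------------------------------

    def fit(self, progress: bool = False) -> OrphanStudyResult:
        cfg = self.config
        genes = self.genes
        valid = {g: m for g, m in genes.items() if m.valid_cds and m.protein}
        labels = {g: m.orphan for g, m in genes.items()}
        species = {g: "ppa" for g in valid}
        species.update({x: "pex" for x in self.pex_proteins})
        proteins = {g: m.protein for g, m in valid.items()}
        proteins.update(self.pex_proteins)

        logger.info("building similarity graph over %d proteins", len(proteins))
        graph = build_graph(proteins, min_normalized_score=cfg.edge_threshold)
        raw_clusters, converged = markov_cluster(graph, inflation=cfg.mcl_inflation)
        if not converged:
            logger.warning("MCL flagged non-convergence")
        clusters, exclusions = categorize_clusters(raw_clusters, labels, species)

        cds_of = {g: m.cds for g, m in valid.items()}
        cds_of.update(self.pex_cds)

        drops: list[dict] = []

        def aligned(cid: str, members: list[str]) -> CodonAlignment | None:
            try:
                if len({proteins[m] for m in members}) == 1:
                    msa = [(m, proteins[m]) for m in members]  # already identical
                else:
                    msa = progressive_align([(m, proteins[m]) for m in members])
                aln = backtranslate(msa, cds_of)
            except (BacktranslationError, ValueError) as exc:
                drops.append(
                    {"cluster_id": cid, "reason": f"alignment:{exc}"}
                )
                return None
            if not filter_min_length(aln, cfg.min_alignment_nt):
                drops.append(
                    {
                        "cluster_id": cid,
                        "reason": f"short_alignment:{aln.n_columns}nt",
                    }
                )
                return None
            return aln

        ortholog_alns: list[tuple[str, CodonAlignment]] = []
        paralog_alns: list[tuple[str, CodonAlignment]] = []
        memberships: dict[str, dict[str, list[str]]] = {
            ds: {} for ds in DATASETS
        }
        for rec in clusters:
            ppa = [g for g in rec.ppa_members if g in valid]
            if rec.in_ortholog:
                aln = aligned(rec.cluster_id, rec.ppa_members + rec.pex_members)
                if aln is not None:
                    ortholog_alns.append((rec.cluster_id, aln))
                    memberships["ortholog"][rec.cluster_id] = ppa
            if rec.in_paralog and len(ppa) >= 2:
                # the paralog dataset drops the sister-species members
                aln = aligned(f"{rec.cluster_id}.para", ppa)
                if aln is not None:
                    paralog_alns.append((f"{rec.cluster_id}.para", aln))
                    memberships["paralog"][f"{rec.cluster_id}.para"] = ppa

        clade_pairs = build_clade_pairs(valid, self.variants_a1, self.variants_a2)
        clade_alns: list[tuple[str, CodonAlignment]] = []
        for gid in sorted(clade_pairs):
            aln = clade_pairs[gid]
            if not filter_min_length(aln, cfg.min_alignment_nt):
                drops.append(
                    {"cluster_id": gid, "reason": f"short_alignment:{aln.n_columns}nt"}
                )
                continue
            clade_alns.append((gid, aln))
            memberships["cladeAB"][gid] = [gid]

        selection = {}
        for name, alns in (
            ("ortholog", ortholog_alns),
            ("paralog", paralog_alns),
            ("cladeAB", clade_alns),
        ):
            logger.info("fitting %d %s clusters", len(alns), name)
            selection[name] = run_dataset(alns, name, alpha=cfg.alpha,
                                          progress=progress)

        # -- expression and peptides ---------------------------------------
        gene_ids = sorted(genes)
        fpkm = self.fpkm.reindex(gene_ids).fillna(0.0)
        flags = expressed_flags(fpkm, cfg.fpkm_expressed, cfg.fpkm_robust)
        class_series = pd.Series(
            ["orphan" if labels[g] else "conserved" for g in gene_ids],
            index=gene_ids,
        )
        sat = saturation(
            fpkm,
            class_series,
            thresholds=(cfg.fpkm_expressed, cfg.fpkm_robust),
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
        )
        de_sat = de_saturation(
            self.de_sets, class_series, n_permutations=cfg.n_permutations,
            seed=cfg.seed,
        )
        de_flag = de_membership(self.de_sets, gene_ids)
        proteome = {g: genes[g].protein for g in gene_ids if genes[g].protein}
        hits, pep_flag = match_peptides(self.peptides, proteome)

        # -- evidence integration ------------------------------------------
        sel_evidence = ev.gene_selection_evidence(
            selection,
            memberships,
            gene_ids,
            omega_liberal=cfg.omega_liberal,
            alpha=cfg.alpha,
        )
        frame = sel_evidence
        frame["orphan"] = pd.Series(labels).reindex(gene_ids)
        for col in ("max_fpkm", "expressed", "robust", "zero_everywhere"):
            frame[col] = flags[col].reindex(gene_ids)
        frame["in_de_set"] = de_flag.reindex(gene_ids).fillna(False)
        frame["peptide"] = pep_flag.reindex(gene_ids).fillna(False)
        frame["exon_count"] = [genes[g].exon_count for g in gene_ids]
        frame["transcript_length"] = [genes[g].transcript_length for g in gene_ids]
        frame["gc_fraction"] = [genes[g].gc_fraction for g in gene_ids]
        frame["contig_percentile"] = ev.contig_percentile(
            self.contig_lengths,
            pd.Series([genes[g].contig for g in gene_ids], index=gene_ids),
        )
        frame["gene_class"] = ev.classify(frame, cfg)
        candidates = ev.select_validation_candidates(frame, cfg)
        feature_tests = ev.feature_stats(frame)
        summary = ev.summarize(frame, selection, candidates, cfg)

        return OrphanStudyResult(
            config=cfg,
            evidence=frame,
            selection=selection,
            clusters=clusters,
            exclusions=exclusions,
            drops=pd.DataFrame(drops, columns=["cluster_id", "reason"]),
            saturation=sat,
            de_saturation=de_sat,
            peptide_hits=hits,
            candidates=candidates,
            feature_tests=feature_tests,
            summary_dict=summary,
        )
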