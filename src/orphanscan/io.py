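"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (CDS, proteins, peptides, contigs), GFF3 gene models, the
OrthoMCL-style groups dialect (``id: species|gene ...``), TSV tables (orphan
labels, FPKM matrix, DE gene sets, fixed-difference variant tables), flat
key=value run configs, and JSON summaries.  GFF3 and the variant table use
1-based inclusive coordinates on disk; both are converted to the package's
0-based half-open convention here, exactly once.  Writers are atomic (write
to a temp file in the target directory, then rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import gencode
from .records import ClusterRecord, GeneModel, RunConfig

logger = logging.getLogger(__name__)


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a sibling temp file and rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered id -> uppercase sequence dict.

    Duplicate ids and empty records are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with atomic_write(path) as fh:
        SeqIO.write(
            (SeqRecord(Seq(s.upper()), id=i, description="") for i, s in seqs.items()),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff3(
    gff_path: str | Path,
    contigs: dict[str, str],
    labels: dict[str, bool] | None = None,
) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` records.

    ``contigs`` supplies the assembly sequences used to splice out each CDS
    (minus-strand CDS are reverse-complemented before translation).  Genes
    whose CDS length is not divisible by 3 are kept but flagged
    ``valid_cds=False`` (and later excluded from selection analysis) with a
    warning.  Exon/CDS features without a resolvable parent gene are errors.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    known_parents = {f.id for f in db.features_of_type(("gene", "mRNA"))}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            for parent in feat.attributes.get("Parent", []):
                if parent not in known_parents:
                    raise ValueError(
                        f"{ftype} feature at {feat.seqid}:{feat.start} has "
                        f"unknown parent {parent!r}"
                    )
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gene.seqid not in contigs:
            raise ValueError(f"gene {gid} on unknown contig {gene.seqid!r}")
        contig_seq = contigs[gene.seqid]
        exons = sorted(
            (f.start - 1, f.end)  # 1-based inclusive -> 0-based half-open
            for f in db.children(gene, featuretype="exon")
        )
        cds_parts = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if not cds_parts:
            cds_parts = exons
        if not exons:
            exons = cds_parts
        spliced = "".join(contig_seq[s:e] for s, e in cds_parts)
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        valid = len(spliced) % 3 == 0
        if not valid:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; excluded from "
                "selection analysis",
                gid,
                len(spliced),
            )
            protein = ""
        else:
            from .msa import strip_terminal_stop

            spliced = strip_terminal_stop(spliced)
            protein = gencode.translate_cds(spliced)
            if "*" in protein:
                valid = False
                logger.warning("gene %s: internal stop codon in CDS", gid)
        genes[gid] = GeneModel(
            gene_id=gid,
            contig=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds=spliced,
            protein=protein,
            orphan=bool(labels.get(gid, False)) if labels else False,
            valid_cds=valid,
        )
    return genes


def write_gff3(genes: dict[str, GeneModel], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for gid in genes:
            g = genes[gid]
            start = min(s for s, _ in g.exons) + 1
            end = max(e for _, e in g.exons)
            fh.write(
                f"{g.contig}\torphanscan\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={gid}\n"
            )
            mid = f"{gid}.t1"
            fh.write(
                f"{g.contig}\torphanscan\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\torphanscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}\n"
                )
                fh.write(
                    f"{g.contig}\torphanscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds{k};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# groups dialect
# ---------------------------------------------------------------------------


def read_groups(path: str | Path) -> list[ClusterRecord]:
    """Parse ``cluster_id: species|gene species|gene ...`` lines."""
    clusters: list[ClusterRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing ':' separator")
            cid, members_str = line.split(":", 1)
            members = []
            for token in members_str.split():
                if "|" not in token:
                    raise ValueError(
                        f"{path}:{lineno}: member token {token!r} lacks a "
                        "species|gene separator"
                    )
                sp, gid = token.split("|", 1)
                members.append((sp, gid))
            clusters.append(ClusterRecord(cluster_id=cid.strip(), members=members))
    return clusters


def write_groups(clusters: list[ClusterRecord], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for c in clusters:
            members = " ".join(f"{sp}|{gid}" for sp, gid in c.members)
            fh.write(f"{c.cluster_id}: {members}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> dict[str, bool]:
    """gene_id -> is_orphan from a two-column TSV (label: orphan|conserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id and label")
    bad = set(df["label"].unique()) - {"orphan", "conserved"}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return dict(zip(df["gene_id"], df["label"] == "orphan"))


def write_labels(labels: dict[str, bool], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("gene_id\tlabel\n")
        for gid, orphan in labels.items():
            fh.write(f"{gid}\t{'orphan' if orphan else 'conserved'}\n")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def write_fpkm(fpkm: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fpkm.to_csv(fh, sep="\t", index_label="gene_id")


def read_de_sets(path: str | Path) -> list[set[str]]:
    """TSV with columns set_id, gene_id -> list of gene-id sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [set(sub["gene_id"]) for _, sub in df.groupby("set_id", sort=True)]


def write_de_sets(sets: list[set[str]], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("set_id\tgene_id\n")
        for k, s in enumerate(sets, start=1):
            for gid in sorted(s):
                fh.write(f"set{k}\t{gid}\n")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Fixed-difference SNVs: columns contig, pos (1-based), ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int,
                                            "ref": str, "alt": str})
    need = {"contig", "pos", "ref", "alt"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    for col in ("ref", "alt"):
        bad = ~df[col].str.upper().isin(list("ACGT"))
        if bad.any():
            raise ValueError(f"{path}: non-SNV alleles in column {col}")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config and JSON
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> RunConfig:
    """Flat ``key = value`` text file; unknown keys are errors."""
    cfg = RunConfig()
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
    cfg.validate()
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
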