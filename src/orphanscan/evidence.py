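"""Combine selection, expression, and peptide evidence into gene classes.

Every P. pacificus gene ends up in exactly one of five classes:

* ``conserved`` - genes with homologs outside the restricted taxon;
* ``coding_orphan`` - orphans with significant negative selection
  (omega < 1 and q < alpha in any dataset) or direct peptide evidence;
* ``ncRNA_candidate`` - orphans robustly expressed (FPKM >= 10 somewhere)
  with no sign of strong negative selection;
* ``artifact_or_pseudogene`` - orphans with no expression above the
  detection threshold and no sign of strong negative selection;
* ``unassigned`` - orphans with weak expression (1 <= max FPKM < 10) and no
  selection or peptide support; the four named classes are not exhaustive.

"Strong negative selection" for the two negative classes means the liberal
rule (omega < 0.6 in any dataset) by default; the precedence order
coding > ncRNA > artifact resolves overlaps.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .records import DATASETS, RunConfig

FEATURES = ("transcript_length", "exon_count", "gc_fraction", "contig_percentile")


def gene_selection_evidence(
    selection: dict[str, pd.DataFrame],
    memberships: dict[str, dict[str, list[str]]],
    gene_ids: list[str],
    omega_liberal: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Propagate per-cluster selection results to genes, per dataset.

    ``memberships[dataset][cluster_id]`` lists the focal-species genes of the
    cluster; a gene may appear in at most one cluster per dataset (an error
    otherwise, since the clustering is a partition).  A gene inherits its
    cluster's omega-hat and q-value.  The liberal flag is omega < 0.6 in any
    dataset; the conservative flag is omega < 1 with q < alpha in any.
    """
    frame = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for ds in DATASETS:
        omega = pd.Series(np.nan, index=frame.index)
        qval = pd.Series(np.nan, index=frame.index)
        signif = pd.Series(False, index=frame.index)
        table = selection.get(ds)
        members = memberships.get(ds, {})
        if table is not None and not table.empty:
            by_cluster = table.set_index("cluster_id")
            seen: dict[str, str] = {}
            for cid, genes in members.items():
                if cid not in by_cluster.index:
                    continue
                row = by_cluster.loc[cid]
                for g in genes:
                    if g not in frame.index:
                        continue
                    if g in seen:
                        raise ValueError(
                            f"gene {g} is in clusters {seen[g]} and {cid} of "
                            f"dataset {ds}: not a partition"
                        )
                    seen[g] = cid
                    omega.loc[g] = row["omega"]
                    qval.loc[g] = row["q_value"]
                    signif.loc[g] = bool(row["significant"])
        frame[f"omega_{ds}"] = omega
        frame[f"q_{ds}"] = qval
        frame[f"significant_{ds}"] = signif
        frame[f"liberal_{ds}"] = omega < omega_liberal
    lib_cols = [f"liberal_{ds}" for ds in DATASETS]
    sig_cols = [f"significant_{ds}" for ds in DATASETS]
    omega_cols = [f"omega_{ds}" for ds in DATASETS]
    frame["liberal_any"] = frame[lib_cols].any(axis=1)
    frame["conservative_any"] = frame[sig_cols].any(axis=1)
    frame["n_liberal_datasets"] = frame[lib_cols].sum(axis=1).astype(int)
    frame["selection_coverage"] = frame[omega_cols].notna().sum(axis=1).astype(int)
    return frame


def venn3(sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts of the 7 regions of a three-set Venn diagram.

    Keys are subsets of the three set names joined by ``&`` (e.g. ``"A"``,
    ``"A&B"``, ``"A&B&C"``); regions partition the union.
    """
    names = list(sets)
    if len(names) != 3:
        raise ValueError("venn3 needs exactly three sets")
    regions: dict[str, int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                set(), *(sets[n] for n in names if n not in combo)
            )
            regions["&".join(combo)] = len(inside - outside)
    return regions


def classify(evidence: pd.DataFrame, config: RunConfig | None = None) -> pd.Series:
    """Assign the final class per gene (precedence: conserved, coding,
    ncRNA candidate, artifact/pseudogene, unassigned)."""
    cfg = config or RunConfig()
    no_strong = ~(
        evidence["conservative_any"]
        if cfg.ncrna_rule == "conservative"
        else evidence["liberal_any"]
    )
    coding = evidence["conservative_any"] | evidence["peptide"]
    out = pd.Series("unassigned", index=evidence.index, name="gene_class")
    orphan = evidence["orphan"]
    out[~orphan] = "conserved"
    out[orphan & coding] = "coding_orphan"
    out[orphan & ~coding & evidence["robust"] & no_strong] = "ncRNA_candidate"
    out[orphan & ~coding & ~evidence["expressed"] & no_strong & ~evidence["robust"]] = (
        "artifact_or_pseudogene"
    )
    return out


def select_validation_candidates(
    evidence: pd.DataFrame, config: RunConfig | None = None
) -> list[str]:
    """Orphans worth chasing by PCR: significant negative selection, FPKM = 0
    in every sample, a liberal omega call in at least 2 of the 3 datasets,
    and more than 2 exons in the predicted gene model."""
    cfg = config or RunConfig()
    mask = (
        evidence["orphan"]
        & evidence["conservative_any"]
        & evidence["zero_everywhere"]
        & (evidence["n_liberal_datasets"] >= cfg.min_candidate_datasets)
        & (evidence["exon_count"] >= cfg.min_candidate_exons)
    )
    return sorted(evidence.index[mask])


def rank_sum_test(x, y, exact_limit: int = 400) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when n1*n2 is small and there are no ties, otherwise
    the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size * y.size <= exact_limit and not has_ties) else "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def feature_stats(
    evidence: pd.DataFrame, features: tuple[str, ...] = FEATURES
) -> pd.DataFrame:
    """Pairwise rank-sum tests of gene features across the assigned classes.

    Empty classes are skipped (noted with a NaN p-value row is *not* added;
    pairs simply do not appear)."""
    classes = [c for c in evidence["gene_class"].unique() if c != "unassigned"]
    classes.sort()
    rows = []
    for feat in features:
        for a, b in itertools.combinations(classes, 2):
            xa = evidence.loc[evidence["gene_class"] == a, feat].dropna()
            xb = evidence.loc[evidence["gene_class"] == b, feat].dropna()
            if len(xa) == 0 or len(xb) == 0:
                continue
            rows.append(
                {
                    "feature": feat,
                    "class_a": a,
                    "class_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "median_a": float(xa.median()),
                    "median_b": float(xb.median()),
                    "p_value": rank_sum_test(xa, xb),
                }
            )
    return pd.DataFrame(rows)


def contig_percentile(
    contig_lengths: dict[str, int], gene_to_contig: pd.Series
) -> pd.Series:
    """Per-gene percentile of its contig in the assembly's length ranking.

    The largest contig has percentile 100/n, the smallest 100; ties share the
    minimum (best) rank.  Genes on unknown contigs raise.
    """
    names = sorted(contig_lengths, key=lambda c: (-contig_lengths[c], c))
    lengths = [contig_lengths[c] for c in names]
    n = len(names)
    rank: dict[str, int] = {}
    for i, c in enumerate(names):
        if i > 0 and lengths[i] == lengths[i - 1]:
            rank[c] = rank[names[i - 1]]
        else:
            rank[c] = i + 1
    missing = set(gene_to_contig.unique()) - set(names)
    if missing:
        raise ValueError(f"genes on unknown contigs: {sorted(missing)}")
    return gene_to_contig.map(lambda c: 100.0 * rank[c] / n).rename(
        "contig_percentile"
    )


def omega_cumulative_curve(
    omegas, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Cumulative proportion of clusters with omega-hat below each threshold."""
    vals = np.asarray([w for w in omegas if np.isfinite(w)], float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 2.01, 0.05), 2)
    if vals.size == 0:
        prop = np.zeros(len(thresholds))
    else:
        prop = np.array([(vals < t).mean() for t in thresholds])
    return pd.DataFrame({"omega_threshold": thresholds, "proportion": prop})


def summarize(evidence: pd.DataFrame, selection: dict[str, pd.DataFrame],
              candidates: list[str], config: RunConfig | None = None) -> dict:
    """Aggregate the per-gene evidence table into the report dictionary;
    every number here is re-derivable from the evidence/selection tables."""
    cfg = config or RunConfig()
    orphan = evidence["orphan"]
    summary = {
        "n_genes": int(len(evidence)),
        "n_orphan": int(orphan.sum()),
        "n_conserved": int((~orphan).sum()),
        "class_counts": evidence["gene_class"].value_counts().to_dict(),
        "expressed": {
            "orphan": int((orphan & evidence["expressed"]).sum()),
            "conserved": int((~orphan & evidence["expressed"]).sum()),
        },
        "robust": {
            "orphan": int((orphan & evidence["robust"]).sum()),
            "conserved": int((~orphan & evidence["robust"]).sum()),
        },
        "zero_everywhere_orphan": int((orphan & evidence["zero_everywhere"]).sum()),
        "peptide": {
            "orphan": int((orphan & evidence["peptide"]).sum()),
            "conserved": int((~orphan & evidence["peptide"]).sum()),
        },
        "negative_selection": {
            "liberal_orphan": int((orphan & evidence["liberal_any"]).sum()),
            "conservative_orphan": int((orphan & evidence["conservative_any"]).sum()),
        },
        "datasets": {},
        "venn_liberal": venn3(
            {
                ds: set(evidence.index[orphan & evidence[f"liberal_{ds}"]])
                for ds in DATASETS
            }
        ),
        "venn_conservative": venn3(
            {
                ds: set(evidence.index[orphan & evidence[f"significant_{ds}"]])
                for ds in DATASETS
            }
        ),
        "n_validation_candidates": len(candidates),
        "validation_candidates": list(candidates),
        "thresholds": {
            "fpkm_expressed": cfg.fpkm_expressed,
            "fpkm_robust": cfg.fpkm_robust,
            "omega_liberal": cfg.omega_liberal,
            "alpha": cfg.alpha,
            "min_alignment_nt": cfg.min_alignment_nt,
        },
    }
    for ds, table in selection.items():
        if table is None or table.empty:
            summary["datasets"][ds] = {"n_clusters": 0, "n_significant": 0}
            continue
        summary["datasets"][ds] = {
            "n_clusters": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "median_omega": float(table["omega"].median()),
        }
    return summary
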