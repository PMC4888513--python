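"""Homology clustering: similarity graph, Markov clustering, categorization.

All-vs-all local alignment (Smith-Waterman via Biopython's PairwiseAligner,
after a shared-4-mer prescreen) yields normalized similarities
score / min(self-score); edges at or above a threshold form an undirected
weighted graph which Markov clustering (expansion 2, inflation 2) partitions
into homology clusters.  Clusters are then categorized: clusters mixing
focal-species orphan and conserved genes ("hybrid") and clusters private to
the sister species are excluded; the remainder feed the ortholog dataset
(>= 1 gene from each species) and the paralog dataset (>= 2 focal-species
genes, sister-species members removed).
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .msa import CodonAlignment, implant_snvs, variants_to_cds_coords
from .records import ClusterRecord, GeneModel

logger = logging.getLogger(__name__)

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHABET = set(str(_B62.alphabet))


def _aligner(match=None, mismatch=None, gap_open=11.0, gap_extend=1.0,
             mode="local") -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = mode
    if match is None:
        a.substitution_matrix = _B62
    else:
        a.match_score = match
        a.mismatch_score = mismatch
    a.open_gap_score = -(gap_open)
    a.extend_gap_score = -(gap_extend)
    return a


def smith_waterman(
    a: str,
    b: str,
    match: float | None = None,
    mismatch: float | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Best local-alignment score (BLOSUM62 + affine gaps by default).

    With ``match``/``mismatch`` given, simple match/mismatch scoring is used
    instead (and ``gap_open``/``gap_extend`` are the positive penalties).
    Scores are never negative; unknown residues raise.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if match is None:
        for name, s in (("a", a), ("b", b)):
            bad = set(s) - _B62_ALPHABET
            if bad:
                raise ValueError(f"unknown residue(s) {sorted(bad)} in sequence {name}")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    return max(0.0, float(aligner.score(a, b)))


def _kmer_sets(seqs: dict[str, str], k: int) -> dict[str, set[str]]:
    return {
        i: {s[j : j + k] for j in range(max(len(s) - k + 1, 0))}
        for i, s in seqs.items()
    }


def build_graph(
    proteins: dict[str, str],
    min_normalized_score: float = 0.3,
    kmer: int = 4,
    min_kmer_fraction: float = 0.1,
) -> nx.Graph:
    """Similarity graph over proteins.

    Node ids are the protein ids; edge weight is SW score normalized by the
    smaller self-score, kept when >= ``min_normalized_score``.  Before any
    alignment, a pair must share at least ``min_kmer_fraction`` of the
    smaller protein's distinct ``kmer``-mers: homologous pairs below ~20 %
    divergence share ~0.8^kmer of them (0.41 at k=4), unrelated pairs of any
    length around 1 %, so the all-vs-all stage stays desk-scale.  Very short
    proteins (< 2*kmer residues) bypass the prescreen.
    """
    import scipy.sparse as sp

    g = nx.Graph()
    ids = sorted(proteins)
    g.add_nodes_from(ids)
    if min_normalized_score > 1.0:
        return g
    aligner = _aligner()
    self_scores = {i: float(aligner.score(proteins[i], proteins[i])) for i in ids}
    ksets = _kmer_sets(proteins, kmer)

    # shared distinct k-mer counts for all pairs at once (sparse product)
    vocab: dict[str, int] = {}
    rows, cols = [], []
    for r, i in enumerate(ids):
        for km in ksets[i]:
            cols.append(vocab.setdefault(km, len(vocab)))
            rows.append(r)
    X = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(ids), max(len(vocab), 1)),
    )
    counts = sp.triu(X @ X.T, k=1).tocoo()
    set_sizes = np.array([len(ksets[i]) for i in ids])
    needed = np.maximum(
        1,
        np.ceil(
            min_kmer_fraction
            * np.minimum(set_sizes[counts.row], set_sizes[counts.col])
        ),
    )
    keep = counts.data >= needed
    candidates: set[tuple[str, str]] = {
        (ids[r], ids[c])
        for r, c in zip(counts.row[keep], counts.col[keep])
    }
    # very short proteins have too few k-mers to prescreen reliably
    short = [i for i in ids if len(proteins[i]) < 2 * kmer]
    for i in short:
        for j in ids:
            if j != i:
                candidates.add((min(i, j), max(i, j)))
    for i, j in sorted(candidates):
        score = float(aligner.score(proteins[i], proteins[j]))
        if score <= 0:
            continue
        norm = score / min(self_scores[i], self_scores[j])
        if norm >= min_normalized_score:
            g.add_edge(i, j, weight=min(norm, 1.0))
    return g


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    pruning: float = 1e-5,
    max_iterations: int = 100,
    tol: float = 1e-8,
) -> tuple[list[list[str]], bool]:
    """Markov clustering of a weighted graph into a partition of its nodes.

    Classic MCL: add self-loops, column-normalize, then alternate expansion
    (matrix power) and inflation (entrywise power + renormalization), pruning
    tiny entries, until the matrix is (numerically) idempotent.  Clusters are
    read off the attractor rows; overlaps are resolved deterministically by
    merging, so the result is always a partition.  Returns (clusters sorted
    by their smallest member, converged flag); non-convergence is reported
    with the partial clustering flagged by the caller.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    np.fill_diagonal(M, np.maximum(M.diagonal(), 1.0))  # self-loops
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iterations):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < pruning] = 0.0
        col = M.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        M /= col
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("Markov clustering did not converge; partial result")

    # attractors have mass on their own diagonal; their rows define clusters
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    thresh = pruning
    for i in range(n):
        if M[i, i] > thresh:
            for j in np.nonzero(M[i] > thresh)[0]:
                union(i, int(j))
    groups: dict[int, list[str]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(nodes[k])
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda c: c[0])
    return clusters, converged


def categorize_clusters(
    clusters: list[list[str]],
    labels: dict[str, bool],
    species: dict[str, str],
) -> tuple[list[ClusterRecord], pd.DataFrame]:
    """Tag clusters with counts, category, and dataset membership.

    ``labels`` maps focal-species gene ids to the orphan flag; ``species``
    maps every member to its species tag ("ppa" focal, "pex" sister).
    Hybrid clusters (orphan and conserved focal genes together) and
    sister-species-specific clusters are excluded from both selection
    datasets and listed in the exclusion report.
    """
    records: list[ClusterRecord] = []
    exclusions = []
    for k, members in enumerate(clusters):
        tagged = []
        n_orph = n_cons = n_pex = 0
        for gid in members:
            sp = species.get(gid)
            if sp is None:
                raise ValueError(f"gene {gid} has no species tag")
            tagged.append((sp, gid))
            if sp == "pex":
                n_pex += 1
            else:
                if gid not in labels:
                    raise ValueError(f"focal gene {gid} has no orphan/conserved label")
                if labels[gid]:
                    n_orph += 1
                else:
                    n_cons += 1
        n_ppa = n_orph + n_cons
        if n_ppa == 0:
            category = "pex_specific"
        elif n_orph >= 1 and n_cons >= 1:
            category = "hybrid"
        elif n_orph >= 1:
            category = "orphan"
        else:
            category = "conserved"
        excluded = category in ("hybrid", "pex_specific")
        rec = ClusterRecord(
            cluster_id=f"c{k + 1:05d}",
            members=tagged,
            ppa_orphan=n_orph,
            ppa_conserved=n_cons,
            pex=n_pex,
            category=category,
            in_ortholog=not excluded and n_ppa >= 1 and n_pex >= 1,
            in_paralog=not excluded and n_ppa >= 2,
        )
        records.append(rec)
        if excluded:
            exclusions.append(
                {
                    "cluster_id": rec.cluster_id,
                    "category": category,
                    "n_members": len(members),
                    "members": " ".join(members),
                }
            )
    return records, pd.DataFrame(
        exclusions, columns=["cluster_id", "category", "n_members", "members"]
    )


def build_clade_pairs(
    genes: dict[str, GeneModel],
    variants_a1: pd.DataFrame,
    variants_a2: pd.DataFrame,
) -> dict[str, CodonAlignment]:
    """Per-gene two-allele alignments for the two intra-species lineages.

    Each focal gene's fixed differences for clades A1 and A2 are implanted
    into its reference CDS, giving one size-2 "cluster" per gene (every gene
    is covered, singletons included; genes without fixed differences yield
    identical alleles, flagged downstream).  Variants on minus-strand genes
    are complemented when mapped into CDS coordinates.
    """
    by_contig_1: dict[str, list[tuple[int, str, str]]] = {}
    by_contig_2: dict[str, list[tuple[int, str, str]]] = {}
    for table, store in ((variants_a1, by_contig_1), (variants_a2, by_contig_2)):
        for row in table.itertuples(index=False):
            store.setdefault(str(row.contig), []).append(
                (int(row.pos), str(row.ref), str(row.alt))
            )
    pairs: dict[str, CodonAlignment] = {}
    for gid in sorted(genes):
        gene = genes[gid]
        if not gene.valid_cds:
            continue
        snvs1 = variants_to_cds_coords(gene, by_contig_1.get(gene.contig, []))
        snvs2 = variants_to_cds_coords(gene, by_contig_2.get(gene.contig, []))
        allele1 = implant_snvs(gene.cds, snvs1)
        allele2 = implant_snvs(gene.cds, snvs2)
        pairs[gid] = CodonAlignment.from_ungapped(
            [f"{gid}|A1", f"{gid}|A2"], [allele1, allele2]
        )
    return pairs
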