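"""Phylogeny utilities: a light postorder tree, random unrooted trees, NJ.

Unrooted trees are represented, and written to newick, with a trifurcating
root (the usual convention for unrooted topologies).  Branch lengths are in
substitutions per codon site.
"""

from __future__ import annotations

import io
from collections import defaultdict

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


class PhyloTree:
    """A rooted-representation phylogeny stored in postorder arrays.

    ``edge_length[i]`` is the length of the edge above node ``i`` (0 for the
    root).  Node indices are a postorder ordering with the root last, which is
    exactly the traversal order needed by the pruning algorithm.
    """

    def __init__(
        self,
        children: list[list[int]],
        edge_length: np.ndarray,
        labels: list[str | None],
    ):
        self.children = children
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = labels
        self.n_nodes = len(children)
        self.root = self.n_nodes - 1
        self.leaves = [i for i, ch in enumerate(children) if not ch]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nodes = list(t.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = []
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = []
        for i, nd in enumerate(nodes):
            children.append([index[id(c)] for c in nd.child_nodes()])
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon is not None else nd.label)
            else:
                labels.append(None)
        return cls(children, lengths, labels)

    @classmethod
    def pair(cls, a: str, b: str, distance: float) -> "PhyloTree":
        """Two taxa joined by a single path of the given total length."""
        half = distance / 2.0
        return cls([[], [], [0, 1]], np.array([half, half, 0.0]), [a, b, None])

    @classmethod
    def star(cls, taxa: list[str], lengths: list[float]) -> "PhyloTree":
        n = len(taxa)
        children = [[] for _ in range(n)] + [list(range(n))]
        return cls(
            children,
            np.concatenate([np.asarray(lengths, float), [0.0]]),
            list(taxa) + [None],
        )

    # -- accessors ----------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            [list(c) for c in self.children],
            self.edge_length.copy(),
            list(self.labels),
        )

    def to_newick(self) -> str:
        def sub(i: int) -> str:
            if not self.children[i]:
                return f"{self.labels[i]}:{self.edge_length[i]:.10g}"
            inner = ",".join(sub(c) for c in self.children[i])
            if i == self.root:
                return f"({inner})"
            return f"({inner}):{self.edge_length[i]:.10g}"

        return sub(self.root) + ";"

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between leaves (small trees; used in tests)."""
        adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
        for i, ch in enumerate(self.children):
            for c in ch:
                adj[i].append((c, self.edge_length[c]))
                adj[c].append((i, self.edge_length[c]))
        taxa = self.taxa
        n = len(taxa)
        dm = np.zeros((n, n))
        for a, src in enumerate(self.leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for b, dst in enumerate(self.leaves):
                dm[a, b] = dist[dst]
        return taxa, dm


def simulate_tree(n_taxa: int, total_depth: float, seed: int) -> str:
    """Draw a random unrooted binary topology over ``n_taxa`` leaves.

    Branch lengths are drawn uniformly and rescaled so that the mean pairwise
    leaf-to-leaf path length equals ``total_depth``.  For two taxa the tree is
    the single edge of length ``total_depth``.  Identical seeds yield
    byte-identical newick strings.
    """
    if n_taxa < 2:
        raise ValueError("a phylogeny needs at least 2 taxa")
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    if n_taxa == 2:
        h = total_depth / 2.0
        return f"({taxa[0]}:{h:.10g},{taxa[1]}:{h:.10g});"

    # grow an unrooted topology by splitting random edges
    next_node = n_taxa  # leaves are 0..n_taxa-1
    center = next_node
    next_node += 1
    edges: list[tuple[int, int]] = [(center, 0), (center, 1), (center, 2)]
    for leaf in range(3, n_taxa):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        m = next_node
        next_node += 1
        edges.extend([(u, m), (m, v), (m, leaf)])

    lengths = {e: float(rng.uniform(0.5, 1.5)) for e in edges}
    adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
    for (u, v), w in lengths.items():
        adj[u].append((v, w))
        adj[v].append((u, w))

    # mean pairwise leaf distance, for rescaling
    total, count = 0.0, 0
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(src + 1, n_taxa):
            total += dist[dst]
            count += 1
    scale = total_depth / (total / count)

    def sub(node: int, parent: int) -> str:
        kids = [(v, w) for v, w in adj[node] if v != parent]
        if not kids:
            return f"{taxa[node]}"
        parts = []
        for v, w in kids:
            s = sub(v, node)
            parts.append(f"{s}:{w * scale:.10g}")
        return "(" + ",".join(parts) + ")"

    # root at the first internal node -> trifurcating root
    parts = []
    for v, w in adj[center]:
        parts.append(f"{sub(v, center)}:{w * scale:.10g}")
    return "(" + ",".join(parts) + ");"


def nj_tree(ids: list[str], dm: np.ndarray, min_branch: float = 1e-8) -> PhyloTree:
    """Neighbor joining on a pairwise distance matrix.

    Two taxa give the single edge; three give the star with additive branch
    lengths; four or more go through scikit-bio's NJ.  Negative NJ branch
    lengths (possible on non-additive inputs) are clipped to ``min_branch``.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        return PhyloTree.pair(ids[0], ids[1], max(dm[0, 1], min_branch))
    if n == 3:
        a = (dm[0, 1] + dm[0, 2] - dm[1, 2]) / 2.0
        b = (dm[0, 1] + dm[1, 2] - dm[0, 2]) / 2.0
        c = (dm[0, 2] + dm[1, 2] - dm[0, 1]) / 2.0
        lengths = [max(x, min_branch) for x in (a, b, c)]
        return PhyloTree.star(list(ids), lengths)
    dm = 0.5 * (dm + dm.T)  # exact symmetry (path sums can differ in rounding)
    np.fill_diagonal(dm, 0.0)
    sk = _skbio_nj(DistanceMatrix(dm, ids))
    buf = io.StringIO()
    sk.write(buf)
    tree = PhyloTree.from_newick(buf.getvalue())
    tree.edge_length = np.maximum(tree.edge_length, min_branch)
    tree.edge_length[tree.root] = 0.0
    return tree
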