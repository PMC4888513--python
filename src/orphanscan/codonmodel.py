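"""Goldman-Yang (M0) codon substitution model.

The model assigns rate q_ij between sense codons i != j that differ at a
single nucleotide position:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with q_ij = 0 for multi-nucleotide changes, diagonal set so rows sum to zero,
and the matrix scaled so the expected number of substitutions per codon site
per unit time is one (sum_i pi_i * -q_ii = 1).  Branch lengths are therefore
in expected codon substitutions per site.

Transition probabilities P(t) = exp(Qt) are computed by eigendecomposition in
the pi-symmetrized basis (Q is reversible with stationary distribution pi, so
B = D^{1/2} Q D^{-1/2} is symmetric); scipy's scaling-and-squaring expm is the
fallback for degenerate frequency vectors.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from . import gencode
from .gencode import GAP_CODE, N_SENSE
from .trees import PhyloTree

OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (0.05, 50.0)
BRANCH_BOUNDS = (1e-6, 20.0)

_MIN_FREQ = 1e-10


def uniform_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4(seqs) -> np.ndarray:
    """F3x4 codon frequencies from aligned or unaligned nucleotide sequences.

    Position-specific nucleotide frequencies are estimated over the three
    codon positions (gaps ignored), multiplied into codon frequencies,
    restricted to the sense codons and renormalized.  A tiny floor keeps
    every sense codon reachable (degenerate inputs otherwise break the
    reversible eigendecomposition).
    """
    counts = np.zeros((3, 4))
    nt_index = {c: k for k, c in enumerate(gencode.NUCLEOTIDES)}
    for seq in seqs:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            for p in range(3):
                k = nt_index.get(s[i + p])
                if k is not None:
                    counts[p, k] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    pi = np.empty(N_SENSE)
    for i, codon in enumerate(gencode.SENSE_CODONS):
        pi[i] = (
            freqs[0, nt_index[codon[0]]]
            * freqs[1, nt_index[codon[1]]]
            * freqs[2, nt_index[codon[2]]]
        )
    pi = np.maximum(pi, _MIN_FREQ)
    return pi / pi.sum()


def gy94_rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """The scaled 61x61 GY94 rate matrix."""
    if omega <= 0 or kappa <= 0:
        raise ValueError("omega and kappa must be positive")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,) or abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
        raise ValueError("pi must be 61 non-negative frequencies summing to 1")
    Q = np.where(gencode.SINGLE_NT_CHANGE, pi[np.newaxis, :], 0.0)
    Q = Q * np.where(gencode.IS_TRANSITION, kappa, 1.0)
    Q = Q * np.where(gencode.IS_SYNONYMOUS, 1.0, omega)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / rate


class M0SubstitutionModel:
    """A GY94 model instance with cached spectral decomposition."""

    def __init__(self, omega: float, kappa: float, pi: np.ndarray):
        self.omega = float(omega)
        self.kappa = float(kappa)
        self.pi = np.asarray(pi, dtype=float)
        self.Q = gy94_rate_matrix(omega, kappa, self.pi)
        self._sqrt_pi = np.sqrt(self.pi)
        self._use_eig = True
        try:
            B = (self.Q * self._sqrt_pi[:, None]) / self._sqrt_pi[None, :]
            B = 0.5 * (B + B.T)  # symmetrize away rounding noise
            self._eigval, self._eigvec = np.linalg.eigh(B)
            # left/right transforms back to the original basis
            self._right = self._eigvec / self._sqrt_pi[:, None]
            self._left = self._eigvec.T * self._sqrt_pi[None, :]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate pi
            self._use_eig = False

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self._use_eig:
            P = (self._right * np.exp(self._eigval * t)) @ self._left
        else:  # pragma: no cover
            P = scipy.linalg.expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def expected_nt_divergence(self, t: float) -> float:
        """Expected per-nucleotide divergence between two sequences whose
        path length is ``t`` codon substitutions per codon site."""
        P = self.transition_matrix(t)
        joint = self.pi[:, None] * P
        return float((joint * gencode.NT_HAMMING).sum() / 3.0)

    def path_length_for_nt_divergence(self, d: float, t_max: float = 20.0) -> float:
        """Invert the expected-divergence curve by bisection."""
        if d <= 0:
            return 0.0
        lo, hi = 0.0, t_max
        if self.expected_nt_divergence(hi) < d:
            raise ValueError(f"nucleotide divergence {d} is beyond saturation")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.expected_nt_divergence(mid) < d:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def pruning_loglik(
    codes: np.ndarray,
    taxa: list[str],
    tree: PhyloTree,
    model: M0SubstitutionModel,
    weights: np.ndarray | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of a codon alignment on a tree.

    ``codes`` is an (n_seq, n_col) array of sense-codon indices with
    ``GAP_CODE`` for gaps; gap codons contribute a partial likelihood of one
    (missing data).  Per-column scaling guards against underflow, so valid
    input never produces -inf.
    """
    codes = np.asarray(codes)
    n_seq, n_col = codes.shape
    if weights is None:
        weights = np.ones(n_col)
    row_of = {}
    for r, name in enumerate(taxa):
        row_of[name] = r
    leaf_rows = {}
    for node in tree.leaves:
        label = tree.labels[node]
        if label not in row_of:
            raise ValueError(f"tree taxon {label!r} missing from alignment")
        leaf_rows[node] = row_of[label]
    if len(leaf_rows) != n_seq:
        raise ValueError("tree leaves do not match alignment rows")

    partial = [None] * tree.n_nodes
    log_scale = np.zeros(n_col)
    for node in range(tree.n_nodes):  # postorder by construction
        if not tree.children[node]:
            L = np.zeros((n_col, N_SENSE))
            obs = codes[leaf_rows[node]]
            gap = obs == GAP_CODE
            L[gap, :] = 1.0
            idx = np.nonzero(~gap)[0]
            L[idx, obs[idx]] = 1.0
            partial[node] = L
        else:
            L = np.ones((n_col, N_SENSE))
            for child in tree.children[node]:
                P = model.transition_matrix(tree.edge_length[child])
                L = L * (partial[child] @ P.T)
            # rescale to dodge underflow on deep trees / long alignments
            m = L.max(axis=1)
            tiny = m < 1e-280
            if tiny.any():
                m = np.where(m > 0, m, 1.0)
            safe = np.maximum(m, 1e-300)
            L = L / safe[:, None]
            log_scale += np.log(safe)
            partial[node] = L

    site = partial[tree.root] @ model.pi
    site = np.maximum(site, 1e-300)
    return float((weights * (np.log(site) + log_scale)).sum())
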