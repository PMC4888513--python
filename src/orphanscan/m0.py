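"""M0 codon-model fitting, the neutrality LRT, NG86 counting, and FDR control.

The statistical question, per homology cluster: is the single dN/dS ratio
(omega) shared by all sites and branches smaller than one?  The alternative
model H_A estimates omega freely together with kappa and the branch lengths;
the null H_0 re-optimizes kappa and branch lengths with omega pinned at 1.
The LRT statistic 2(lnL_HA - lnL_H0) is referred to chi-square with one
degree of freedom, and p-values are Benjamini-Hochberg adjusted within each
dataset (orthologs, paralogs, intra-species clade pairs).

``M0CodonModel`` / ``M0FitResult`` follow the model/results idiom: the model
is built from a codon alignment (plus an optional phylogeny), ``fit`` returns
a results object carrying estimates, log-likelihoods and diagnostic flags.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import gencode
from .codonmodel import (
    BRANCH_BOUNDS,
    KAPPA_BOUNDS,
    OMEGA_BOUNDS,
    M0SubstitutionModel,
    f3x4,
    pruning_loglik,
)
from .msa import CodonAlignment
from .trees import PhyloTree, nj_tree

N_SENSE_ = gencode.N_SENSE

OMEGA_STARTS = (0.1, 1.0, 3.0)

# codon-level Jukes-Cantor-style correction has 60/61 as its saturation point
_MAX_P = 60.0 / 61.0


def codon_distance_matrix(aln: CodonAlignment) -> tuple[np.ndarray, bool]:
    """Poisson-corrected pairwise codon distances.

    d = -(60/61) ln(1 - p * 61/60) with p the fraction of differing codon
    columns (columns with a gap in either row are skipped).  Saturated pairs
    (p at or beyond the correctable range) fall back to the maximum finite
    distance in the matrix; the second return value flags that this happened.
    """
    codes = aln.codes()
    n = aln.n_seqs
    dm = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a != gencode.GAP_CODE) & (b != gencode.GAP_CODE)
            if ok.sum() == 0:
                saturated.append((i, j))
                continue
            p = float((a[ok] != b[ok]).mean())
            if p >= _MAX_P:
                saturated.append((i, j))
                continue
            d = -_MAX_P * math.log(1.0 - p / _MAX_P)
            dm[i, j] = dm[j, i] = d
    if saturated:
        fallback = dm.max() if dm.max() > 0 else 5.0
        for i, j in saturated:
            dm[i, j] = dm[j, i] = fallback
    return dm, bool(saturated)


def tree_for_alignment(aln: CodonAlignment) -> tuple[PhyloTree, bool]:
    """NJ topology (2 taxa: single edge; 3: star) from corrected distances."""
    dm, saturated = codon_distance_matrix(aln)
    return nj_tree(aln.ids, dm), saturated


@dataclass
class M0FitResult:
    """Estimates and diagnostics from one M0 maximum-likelihood fit."""

    omega: float  # nan when unidentifiable (identical sequences)
    kappa: float
    loglik: float
    branch_lengths: np.ndarray
    tree: PhyloTree
    fixed_omega: float | None
    n_seqs: int
    n_codons: int
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def tree_length(self) -> float:
        return float(self.branch_lengths.sum())

    def summary(self) -> str:
        lines = [
            "M0 codon model fit",
            "-" * 40,
            f"sequences            {self.n_seqs}",
            f"codon columns        {self.n_codons}",
            f"omega (dN/dS)        "
            + ("fixed at %.4g" % self.fixed_omega if self.fixed_omega is not None
               else "%.4f" % self.omega),
            f"kappa (ts/tv)        {self.kappa:.4f}",
            f"tree length          {self.tree_length:.4f} subs/codon site",
            f"log-likelihood       {self.loglik:.4f}",
            f"converged            {self.converged}",
        ]
        if self.flags:
            lines.append(f"flags                {', '.join(self.flags)}")
        return "\n".join(lines)


class M0CodonModel:
    """Goldman-Yang M0 model bound to one codon alignment.

    Parameters
    ----------
    alignment:
        The cluster's codon alignment.
    tree:
        Optional phylogeny; by default an NJ tree (single edge / star for
        two / three sequences) is built from corrected codon distances.
    frequencies:
        Optional 61-vector of codon frequencies; default F3x4 estimated
        from the alignment itself.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree | None = None,
        frequencies: np.ndarray | None = None,
    ):
        if alignment.n_seqs < 2:
            raise ValueError("selection inference needs at least 2 sequences")
        self.alignment = alignment
        self.pi = f3x4(alignment.rows) if frequencies is None else np.asarray(frequencies, float)
        self._saturated = False
        if tree is None:
            tree, self._saturated = tree_for_alignment(alignment)
        self.tree = tree

        codes = alignment.codes()
        # pattern compression: identical columns share one likelihood evaluation
        cols, counts = np.unique(codes.T, axis=0, return_counts=True)
        self._patterns = cols.T.copy()
        self._weights = counts.astype(float)
        self._codes_full = codes
        self._model_cache: dict[tuple[float, float], M0SubstitutionModel] = {}
        self._scratch_tree = self.tree.copy()

        # two-sequence fast path: the pair likelihood is
        # sum_ij n_ij log(pi_i P_ij(t)) plus a pi-only term for half-gapped
        # columns (stationarity: sum_i pi_i P_ij = pi_j)
        self._pair = None
        if alignment.n_seqs == 2:
            a, b = codes[0], codes[1]
            both = (a != gencode.GAP_CODE) & (b != gencode.GAP_CODE)
            pair_i, pair_j = a[both], b[both]
            flat = pair_i.astype(np.int64) * N_SENSE_ + pair_j
            uniq, cnt = np.unique(flat, return_counts=True)
            single = np.concatenate(
                [b[(a == gencode.GAP_CODE) & (b != gencode.GAP_CODE)],
                 a[(b == gencode.GAP_CODE) & (a != gencode.GAP_CODE)]]
            )
            self._pair = (
                (uniq // N_SENSE_).astype(np.intp),
                (uniq % N_SENSE_).astype(np.intp),
                cnt.astype(float),
                single.astype(np.intp),
            )

        masked = codes.T[(codes.T != gencode.GAP_CODE).all(axis=1)]
        self.identical = bool(
            masked.size == 0 or (masked == masked[:, :1]).all()
        )

    # -- likelihood ---------------------------------------------------------

    def _model(self, omega: float, kappa: float) -> M0SubstitutionModel:
        key = (omega, kappa)
        model = self._model_cache.get(key)
        if model is None:
            if len(self._model_cache) > 128:
                self._model_cache.clear()
            model = M0SubstitutionModel(omega, kappa, self.pi)
            self._model_cache[key] = model
        return model

    def loglik(
        self, omega: float, kappa: float, branch_lengths: np.ndarray | None = None
    ) -> float:
        model = self._model(omega, kappa)
        if self._pair is not None and branch_lengths is not None:
            i_idx, j_idx, counts, single = self._pair
            P = model.transition_matrix(float(branch_lengths[0]))
            ll = float(
                (counts * np.log(np.maximum(model.pi[i_idx] * P[i_idx, j_idx],
                                            1e-300))).sum()
            )
            if single.size:
                ll += float(np.log(model.pi[single]).sum())
            return ll
        tree = self._scratch_tree
        if branch_lengths is not None:
            tree.edge_length[:] = 0.0
            for e, t in zip(self._free_edges(), branch_lengths):
                tree.edge_length[e] = t
        else:
            tree.edge_length[:] = self.tree.edge_length
        return pruning_loglik(
            self._patterns,
            self.alignment.ids,
            tree,
            model,
            self._weights,
        )

    def _free_edges(self) -> list[int]:
        """Edges optimized independently.

        For a two-taxon alignment only the total path length is identifiable,
        so a single edge is optimized (its sibling pinned at zero).
        """
        tree = self.tree
        edges = [i for i in range(tree.n_nodes) if i != tree.root]
        if self.alignment.n_seqs == 2:
            return [edges[0]]
        return edges

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        fix_omega: float | None = None,
        starts: tuple[float, ...] = OMEGA_STARTS,
        tol: float = 1e-6,
        max_sweeps: int = 60,
        init: tuple[float, np.ndarray] | None = None,
    ) -> M0FitResult:
        """Maximize the log-likelihood by cyclic coordinate ascent.

        Branch lengths, kappa, and (unless ``fix_omega`` is given) omega are
        optimized in turn with bounded scalar minimization until the
        log-likelihood improves by less than ``tol`` over a full sweep.
        The free-omega fit restarts from several omega values and keeps the
        best; ``init`` can seed kappa/branch lengths (used to warm-start the
        null fit from the alternative fit).
        """
        n_codons = self.alignment.n_codon_columns
        if self.identical:
            # omega is unidentifiable without substitutions; report the
            # zero-divergence likelihood under either hypothesis
            free = self._free_edges()
            bl = np.full(len(free), BRANCH_BOUNDS[0])
            ll = self.loglik(1.0, 2.0, bl)
            return M0FitResult(
                omega=float("nan"),
                kappa=2.0,
                loglik=ll,
                branch_lengths=bl,
                tree=self._tree_with(bl),
                fixed_omega=fix_omega,
                n_seqs=self.alignment.n_seqs,
                n_codons=n_codons,
                converged=True,
                flags=("identical_sequences",),
            )

        omega_starts = (fix_omega,) if fix_omega is not None else starts
        best = None
        for w0 in omega_starts:
            # later restarts inherit the best nuisance estimates so far; they
            # still explore their own omega start
            warm = init if best is None else (best[2], best[3])
            cand = self._fit_from(w0, fix_omega, tol, max_sweeps, warm)
            if best is None or cand[0] > best[0] + 1e-12:
                best = cand
        ll, omega, kappa, bl, converged = best

        flags = []
        if fix_omega is None:
            lo, hi = OMEGA_BOUNDS
            if omega <= lo * 1.5:
                flags.append("omega_lower_boundary")
            if omega >= hi / 1.05:
                flags.append("omega_upper_boundary")
        if self._saturated:
            flags.append("distance_saturation")
        if not converged:
            flags.append("not_converged")
        return M0FitResult(
            omega=omega if fix_omega is None else float(fix_omega),
            kappa=kappa,
            loglik=ll,
            branch_lengths=bl,
            tree=self._tree_with(bl),
            fixed_omega=fix_omega,
            n_seqs=self.alignment.n_seqs,
            n_codons=n_codons,
            converged=converged,
            flags=tuple(flags),
        )

    def _tree_with(self, bl: np.ndarray) -> PhyloTree:
        tree = self.tree.copy()
        tree.edge_length[:] = 0.0
        for e, t in zip(self._free_edges(), bl):
            tree.edge_length[e] = t
        return tree

    def _fit_from(self, omega0, fix_omega, tol, max_sweeps, init):
        free = self._free_edges()
        if init is not None:
            kappa, bl = init[0], init[1].copy()
        else:
            kappa = 2.0
            bl = np.clip(
                [self.tree.edge_length[e] for e in free], *BRANCH_BOUNDS
            )
            if self.alignment.n_seqs == 2:
                bl = np.clip(
                    [self.tree.edge_length.sum()], *BRANCH_BOUNDS
                )
        omega = float(omega0)

        def neg_t(e_idx):
            def f(t):
                trial = bl.copy()
                trial[e_idx] = t
                return -self.loglik(omega, kappa, trial)

            return f

        prev = self.loglik(omega, kappa, bl)
        converged = False
        for _ in range(max_sweeps):
            for e_idx in range(len(free)):
                res = minimize_scalar(
                    neg_t(e_idx),
                    bounds=BRANCH_BOUNDS,
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                if -res.fun >= prev - 1e-12:
                    bl[e_idx] = float(res.x)
            res = minimize_scalar(
                lambda k: -self.loglik(omega, k, bl),
                bounds=KAPPA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-4},
            )
            kappa = float(res.x)
            if fix_omega is None:
                res = minimize_scalar(
                    lambda w: -self.loglik(w, kappa, bl),
                    bounds=OMEGA_BOUNDS,
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                omega = float(res.x)
            cur = self.loglik(omega, kappa, bl)
            if cur - prev < tol:
                converged = True
                prev = max(cur, prev)
                break
            prev = cur
        return prev, omega, kappa, bl, converged


# ---------------------------------------------------------------------------
# NG86 counting (independent of the likelihood machinery)
# ---------------------------------------------------------------------------

_ng86_site_cache: dict[int, tuple[float, float]] = {}
_ng86_path_cache: dict[tuple[int, int], tuple[float, float]] = {}


def _ng86_sites(codon_idx: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each of the nine single-nucleotide changes contributes 1/3 site to the
    synonymous or nonsynonymous total; changes creating stop codons are
    counted as neither (they are not observable substitutions here).
    """
    cached = _ng86_site_cache.get(codon_idx)
    if cached is not None:
        return cached
    codon = gencode.SENSE_CODONS[codon_idx]
    syn = nonsyn = 0.0
    for p in range(3):
        for nt in gencode.NUCLEOTIDES:
            if nt == codon[p]:
                continue
            target = codon[:p] + nt + codon[p + 1 :]
            j = gencode.CODON_INDEX.get(target)
            if j is None:
                continue  # stop codon
            if gencode.AMINO_ACIDS[j] == gencode.AMINO_ACIDS[codon_idx]:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    _ng86_site_cache[codon_idx] = (syn, nonsyn)
    return syn, nonsyn


def _ng86_differences(i: int, j: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all mutational pathways that avoid stop codons."""
    if i == j:
        return 0.0, 0.0
    key = (i, j)
    cached = _ng86_path_cache.get(key)
    if cached is not None:
        return cached
    a, b = gencode.SENSE_CODONS[i], gencode.SENSE_CODONS[j]
    positions = [p for p in range(3) if a[p] != b[p]]
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = a
        cur_idx = i
        syn = nonsyn = 0.0
        valid = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            nxt_idx = gencode.CODON_INDEX.get(nxt)
            if nxt_idx is None:
                valid = False
                break
            if gencode.AMINO_ACIDS[nxt_idx] == gencode.AMINO_ACIDS[cur_idx]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur, cur_idx = nxt, nxt_idx
        if valid:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        # all pathways blocked by stops: classify each position change singly
        syn_tot = nonsyn_tot = 0.0
        for p in positions:
            target = a[:p] + b[p] + a[p + 1 :]
            tj = gencode.CODON_INDEX.get(target)
            if tj is not None and gencode.AMINO_ACIDS[tj] == gencode.AMINO_ACIDS[i]:
                syn_tot += 1.0
            else:
                nonsyn_tot += 1.0
        n_paths = 1
    out = (syn_tot / n_paths, nonsyn_tot / n_paths)
    _ng86_path_cache[key] = out
    return out


@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float | None  # None when dS = 0 or saturated
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    flags: tuple[str, ...] = ()


def ng86_dnds(aln: CodonAlignment) -> NG86Result:
    """Nei-Gojobori (1986) counting estimate of dN, dS and their ratio.

    Pairwise only; columns containing a gap in either sequence are masked.
    Proportions are Jukes-Cantor corrected.  omega is None (flagged) when
    dS = 0 or when either proportion is beyond the correctable range.
    """
    if aln.n_seqs != 2:
        raise ValueError("NG86 is defined for exactly two sequences")
    codes = aln.codes()
    a, b = codes[0], codes[1]
    ok = (a != gencode.GAP_CODE) & (b != gencode.GAP_CODE)
    a, b = a[ok], b[ok]
    if a.size < 1:
        raise ValueError("alignment shorter than one ungapped codon")

    S = N = Sd = Nd = 0.0
    for i, j in zip(a.tolist(), b.tolist()):
        s1, n1 = _ng86_sites(i)
        s2, n2 = _ng86_sites(j)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _ng86_differences(i, j)
        Sd += sd
        Nd += nd

    flags = []

    def jc(p):
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = jc(ps)
    dn = jc(pn)
    if ds is None and dn == 0.0:
        # synonymous divergence beyond the correctable range but zero
        # nonsynonymous divergence: the ratio is still zero
        flags.append("ds_saturated")
        return NG86Result(0.0, float("inf"), 0.0, S, N, Sd, Nd, tuple(flags))
    if ds is None or dn is None:
        flags.append("saturated")
        return NG86Result(float("nan"), float("nan"), None, S, N, Sd, Nd, tuple(flags))
    if ds == 0.0:
        flags.append("ds_zero")
        if dn == 0.0:
            flags.append("identical")
        return NG86Result(dn, ds, None, S, N, Sd, Nd, tuple(flags))
    return NG86Result(dn, ds, dn / ds, S, N, Sd, Nd, tuple(flags))


# ---------------------------------------------------------------------------
# LRT and FDR
# ---------------------------------------------------------------------------


def lrt(loglik_ha: float, loglik_h0: float) -> tuple[float, float]:
    """LRT statistic 2(lnL_HA - lnL_H0) and its chi-square(df=1) p-value.

    Negative differences (numerical noise from the nested optimizations) are
    clipped to zero, giving p = 1.
    """
    if not (math.isfinite(loglik_ha) and math.isfinite(loglik_h0)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (loglik_ha - loglik_h0))
    return stat, float(chi2.sf(stat, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------


def fit_cluster(aln: CodonAlignment) -> dict:
    """Run the H_A (free omega) and H_0 (omega = 1) fits plus the LRT."""
    model = M0CodonModel(aln)
    ha = model.fit()
    if model.identical:
        h0 = ha
        stat, p = 0.0, 1.0
    else:
        h0 = model.fit(fix_omega=1.0, init=(ha.kappa, ha.branch_lengths))
        stat, p = lrt(ha.loglik, h0.loglik)
    flags = set(ha.flags) | set(h0.flags)
    if aln.n_seqs == 2 and not model.identical:
        ng = ng86_dnds(aln)
        if "ds_zero" in ng.flags:
            flags.add("ds_zero")
    return {
        "n_seqs": aln.n_seqs,
        "n_codons": aln.n_codon_columns,
        "omega": ha.omega,
        "kappa": ha.kappa,
        "lnL_HA": ha.loglik,
        "lnL_H0": h0.loglik,
        "lrt_stat": stat,
        "p_value": p,
        "flags": ",".join(sorted(flags)),
    }


def run_dataset(
    clusters: list[tuple[str, CodonAlignment]],
    dataset: str,
    alpha: float = 0.05,
    progress: bool = False,
) -> pd.DataFrame:
    """Fit every cluster of one dataset and BH-adjust p-values within it.

    Per-cluster failures are recorded (flag ``error``) and never abort the
    dataset.  Returns one row per cluster with omega-hat, both
    log-likelihoods, the LRT statistic, p, q, and status flags.
    """
    rows = []
    for k, (cid, aln) in enumerate(clusters):
        try:
            rec = fit_cluster(aln)
        except Exception as exc:  # noqa: BLE001 - propagate per cluster
            rec = {
                "n_seqs": aln.n_seqs,
                "n_codons": aln.n_codon_columns,
                "omega": float("nan"),
                "kappa": float("nan"),
                "lnL_HA": float("nan"),
                "lnL_H0": float("nan"),
                "lrt_stat": float("nan"),
                "p_value": float("nan"),
                "flags": f"error:{type(exc).__name__}",
            }
        rec["cluster_id"] = cid
        rec["dataset"] = dataset
        rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = np.nan
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "q_value"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    df["significant"] = (
        (df["omega"] < 1.0) & (df["q_value"] < alpha) & df["omega"].notna()
    )
    cols = [
        "cluster_id",
        "dataset",
        "n_seqs",
        "n_codons",
        "omega",
        "kappa",
        "lnL_HA",
        "lnL_H0",
        "lrt_stat",
        "p_value",
        "q_value",
        "significant",
        "flags",
    ]
    return df[cols]
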