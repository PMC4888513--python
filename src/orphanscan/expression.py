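"""Expression evidence: FPKM threshold flags and saturation analyses.

Thresholds are inclusive (FPKM >= 1 counts as expressed, >= 10 as robust).
Saturation curves accumulate the number of evidence-positive genes as
RNA-seq samples (or differential-expression gene sets) are added in randomly
permuted orders; the spread over permutations shows how close the sample
collection is to saturating the detectable gene set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (1.0, 10.0)


def expressed_flags(
    fpkm: pd.DataFrame,
    expressed_threshold: float = 1.0,
    robust_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-gene expression flags from a genes x samples FPKM matrix.

    ``expressed``: max FPKM over samples >= expressed_threshold;
    ``robust``: >= robust_threshold; ``zero_everywhere``: all samples exactly
    zero (the stratum used to pick validation candidates).
    """
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    mx = fpkm.max(axis=1)
    return pd.DataFrame(
        {
            "max_fpkm": mx,
            "expressed": mx >= expressed_threshold,
            "robust": mx >= robust_threshold,
            "zero_everywhere": (fpkm == 0).all(axis=1),
        }
    )


def saturation(
    fpkm: pd.DataFrame,
    classes: pd.Series,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Expressed-gene counts as a function of the number of samples included.

    For each random permutation of the sample order and each k = 1..n_samples,
    a gene counts as detected if its running-max FPKM over the first k samples
    reaches the threshold.  Counts are summarized (min, quartiles, max) over
    permutations, per threshold and per gene class.
    """
    if fpkm.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    classes = classes.reindex(fpkm.index)
    values = fpkm.to_numpy()
    n_samples = values.shape[1]
    class_names = sorted(classes.dropna().unique())
    records: dict[tuple[str, float, int], list[int]] = {}
    for _ in range(n_permutations):
        order = rng.permutation(n_samples)
        running = np.maximum.accumulate(values[:, order], axis=1)
        for thr in thresholds:
            detected = running >= thr  # genes x k
            for cname in class_names:
                mask = (classes == cname).to_numpy()
                counts = detected[mask].sum(axis=0)
                for k in range(n_samples):
                    records.setdefault((cname, thr, k + 1), []).append(
                        int(counts[k])
                    )
    rows = []
    for (cname, thr, k), counts in sorted(records.items()):
        arr = np.array(counts)
        rows.append(
            {
                "gene_class": cname,
                "threshold": thr,
                "n_samples": k,
                "min": int(arr.min()),
                "q1": float(np.percentile(arr, 25)),
                "median": float(np.median(arr)),
                "q3": float(np.percentile(arr, 75)),
                "max": int(arr.max()),
            }
        )
    return pd.DataFrame(rows)


def de_saturation(
    de_sets: list[set[str]],
    classes: pd.Series,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative distinct differentially-expressed genes per number of sets.

    Unknown gene ids are ignored (with the count of ignored ids recorded in
    the ``unknown`` attribute of the returned frame).
    """
    known = set(classes.index)
    cleaned = []
    unknown = 0
    for s in de_sets:
        inside = set(s) & known
        unknown += len(s) - len(inside)
        cleaned.append(inside)
    rng = np.random.default_rng(seed)
    class_names = sorted(classes.dropna().unique())
    records: dict[tuple[str, int], list[int]] = {}
    n_sets = len(cleaned)
    for _ in range(n_permutations):
        order = rng.permutation(n_sets)
        union: set[str] = set()
        for k, idx in enumerate(order, start=1):
            union |= cleaned[idx]
            for cname in class_names:
                count = sum(1 for g in union if classes.get(g) == cname)
                records.setdefault((cname, k), []).append(count)
    rows = []
    for (cname, k), counts in sorted(records.items()):
        arr = np.array(counts)
        rows.append(
            {
                "gene_class": cname,
                "n_sets": k,
                "min": int(arr.min()),
                "median": float(np.median(arr)),
                "max": int(arr.max()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["unknown_gene_ids"] = unknown
    return out


def de_membership(de_sets: list[set[str]], gene_ids) -> pd.Series:
    """Flag genes appearing in at least one differential-expression set."""
    union: set[str] = set()
    for s in de_sets:
        union |= set(s)
    return pd.Series([g in union for g in gene_ids], index=gene_ids, name="in_de_set")
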