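"""Matplotlib figures for the study results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_CLASS_COLORS = {
    "orphan": "tab:orange",
    "conserved": "tab:blue",
}


def plot_saturation(sat: pd.DataFrame, ax=None):
    """Median (with min-max band) expressed-gene counts vs samples included."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (cname, thr), sub in sat.groupby(["gene_class", "threshold"]):
        sub = sub.sort_values("n_samples")
        color = _CLASS_COLORS.get(cname)
        style = "-" if thr <= 1.0 else "--"
        ax.plot(
            sub["n_samples"], sub["median"], style, color=color,
            label=f"{cname}, FPKM >= {thr:g}",
        )
        ax.fill_between(sub["n_samples"], sub["min"], sub["max"], alpha=0.15,
                        color=color)
    ax.set_xlabel("RNA-seq samples included")
    ax.set_ylabel("genes with expression evidence")
    ax.legend(fontsize=8)
    return ax


def plot_omega_curves(result, dataset: str, ax=None):
    """Cumulative proportion of clusters under a given omega, per category."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for orphan, name in ((True, "orphan"), (False, "conserved")):
        curve = result.omega_curve(dataset, orphan)
        ax.plot(
            curve["omega_threshold"], curve["proportion"],
            color=_CLASS_COLORS[name], label=f"{name} clusters",
        )
    ax.axvline(result.config.omega_liberal, ls=":", color="grey")
    ax.set_xlabel("omega threshold")
    ax.set_ylabel("cumulative proportion of clusters")
    ax.set_title(f"{dataset} dataset")
    ax.legend(fontsize=8)
    return ax


def plot_class_feature(evidence: pd.DataFrame, feature: str, ax=None):
    """Boxplots of one gene feature across the assigned classes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    classes = [
        c for c in (
            "artifact_or_pseudogene",
            "ncRNA_candidate",
            "coding_orphan",
            "conserved",
        )
        if (evidence["gene_class"] == c).any()
    ]
    data = [evidence.loc[evidence["gene_class"] == c, feature].dropna()
            for c in classes]
    ax.boxplot(data, tick_labels=[c.replace("_", "\n") for c in classes],
               showfliers=False)
    ax.set_ylabel(feature)
    return ax


def save_standard_figures(result, out_dir) -> list:
    """The report's figure set: saturation, omega curves, feature contrasts."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ax = plot_saturation(result.saturation)
    path = out / "saturation.png"
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
    written.append(path)

    for ds in ("ortholog", "paralog", "cladeAB"):
        ax = plot_omega_curves(result, ds)
        path = out / f"omega_{ds}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)

    for feature in ("transcript_length", "exon_count", "gc_fraction",
                    "contig_percentile"):
        ax = plot_class_feature(result.evidence, feature)
        path = out / f"class_{feature}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
    return written
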