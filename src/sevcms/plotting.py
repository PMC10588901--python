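"""Figure bundle for the severity workflow.

Correlation heatmap (input parameter order, not reclustered), per-model ROC
curves, PC1 x PC2 scatter colored by group, scree plot, and stacked
severity-allocation bars.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns


def correlation_heatmap(results, path) -> str:
    fig, ax = plt.subplots(figsize=(8, 7))
    sns.heatmap(results.correlation.r, vmin=-1, vmax=1, cmap="RdBu_r",
                square=True, ax=ax, cbar_kws={"label": "Spearman r"})
    ax.set_title("Spearman correlation (pairwise complete)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def roc_plot(results, path) -> str:
    models = list(results.roc_curves)
    if not models:
        return ""
    fig, axes = plt.subplots(1, len(models), figsize=(4.2 * len(models), 4),
                             squeeze=False)
    for ax, mname in zip(axes[0], models):
        for rr in results.roc_curves[mname]:
            ax.plot(rr.curve[:, 0], rr.curve[:, 1],
                    label=f"{rr.parameter} (AUC {rr.auc_oriented:.2f})", lw=1.2)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(mname)
        if len(results.roc_curves[mname]) <= 8:
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def pca_scatter(results, path) -> str:
    ref = results.reference_pca
    scores = ref.scores
    meta = results.table_pruned.meta
    fig, ax = plt.subplots(figsize=(6, 5))
    for (mname, group), idx in meta.groupby(["model", "group"]).groups.items():
        ax.scatter(scores.iloc[list(idx), 0], scores.iloc[list(idx), 1],
                   label=f"{mname}/{group}", s=22, alpha=0.8)
    ev = 100 * ref.explained_fraction
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def scree_plot(results, path) -> str:
    ref = results.reference_pca
    fig, ax = plt.subplots(figsize=(5.5, 4))
    xs = np.arange(1, len(ref.component_sds) + 1)
    ax.plot(xs, 100 * ref.explained_fraction, "o-")
    ax.axhline(0, color="k", lw=0.5)
    ax2 = ax.twinx()
    ax2.plot(xs, ref.component_sds, "s--", color="gray", alpha=0.6)
    ax2.axhline(results.model.config.sd_threshold, color="red", lw=0.8, ls=":")
    ax.set_xlabel("component")
    ax.set_ylabel("explained variance (%)")
    ax2.set_ylabel("component SD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def allocation_bars(results, path) -> str:
    gt = results.allocation.group_table
    if gt.empty:
        return ""
    k = results.cluster_model.k
    labels = [f"{r.model}\n{r.group}" for r in gt.itertuples(index=False)]
    fig, ax = plt.subplots(figsize=(max(5, 1.1 * len(labels)), 4.5))
    bottoms = np.zeros(len(gt))
    cmap = plt.get_cmap("viridis", k)
    for c in range(1, k + 1):
        vals = gt[f"cluster_{c}"].to_numpy()
        ax.bar(labels, vals, bottom=bottoms, color=cmap(c - 1),
               label=f"cluster {c}")
        bottoms += vals
    ax.set_ylabel("% of group")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def write_all(results, out_dir) -> list[str]:
    out = Path(out_dir)
    written = []
    for fn, name in [
        (correlation_heatmap, "heatmap.png"),
        (roc_plot, "roc.png"),
        (pca_scatter, "pca_scatter.png"),
        (scree_plot, "scree.png"),
        (allocation_bars, "allocation.png"),
    ]:
        try:
            p = fn(results, out / name)
        except Exception:  # plots must never abort the numeric report
            continue
        if p:
            written.append(p)
    return written
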