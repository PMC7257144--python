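"""Best-effort figure rendering. Tables are the contract; every function here
is a thin layer over an analysis result and failures never affect the numbers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats
from scipy.cluster import hierarchy


def _finish(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_scatter(result, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pairs["expression"], result.pairs["level"], s=4, alpha=0.4)
    ax.set_xlabel("expression")
    ax.set_ylabel("methylation level")
    if result.pearson_r is not None:
        ax.set_title(f"r={result.pearson_r:.3f} (p={result.pearson_p:.2g}), "
                     f"n={result.n_genes}", fontsize=9)
    _finish(fig, path)


def correlation_kde(result, path: str | Path, gridsize: int = 80) -> None:
    """2D kernel density (Scott's rule) of the correlation scatter."""
    x = result.pairs["expression"].to_numpy()
    y = result.pairs["level"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    try:
        kde = stats.gaussian_kde(np.vstack([x, y]))
        xi = np.linspace(x.min(), x.max(), gridsize)
        yi = np.linspace(y.min(), y.max(), gridsize)
        xx, yy = np.meshgrid(xi, yi)
        zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        ax.contourf(xx, yy, zz, levels=12, cmap="viridis")
    except np.linalg.LinAlgError:
        ax.scatter(x, y, s=4)
    ax.set_xlabel("expression")
    ax.set_ylabel("methylation level")
    _finish(fig, path)


def ordinal_plot(result, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.table["rank"], result.table["level"], s=3, alpha=0.3,
               label="genes")
    ax.plot(result.table["rank"], result.curve, color="red", lw=1.5,
            label=f"moving average (w={result.ma_window})")
    if 0 < result.boundary_index < len(result.table):
        ax.axvline(result.boundary_index - 0.5, color="grey", lw=1,
                   label="expressed boundary")
    ax.set_xlabel("expression rank")
    ax.set_ylabel("methylation level")
    ax.legend(fontsize=7)
    _finish(fig, path)


def grouping_boxplot(stats_result, path: str | Path, kind: str = "box") -> None:
    groups = sorted(stats_result.values)
    data = [stats_result.values[g] for g in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    if kind == "violin":
        parts = [d for d in data if len(d) > 1]
        if parts:
            ax.violinplot(parts, showmedians=True)
    else:
        ax.boxplot(data, tick_labels=[str(g) for g in groups])
    ax.set_xlabel("expression group (0 = unexpressed)")
    ax.set_ylabel("methylation level")
    _finish(fig, path)


def metagene_plot(profile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(profile.matrix.shape[1])
    for grp, row in profile.matrix.iterrows():
        ax.plot(x, row.to_numpy(), label=f"group {grp}")
    ax.set_xlabel(f"window ({profile.mode})")
    ax.set_ylabel("methylation level")
    ax.legend(fontsize=7)
    _finish(fig, path)


def comparison_plot(diff_result, path: str | Path) -> None:
    tab = diff_result.table
    fig, ax = plt.subplots(figsize=(5, 5))
    sig = tab["is_differential"]
    ax.scatter(tab.loc[~sig, "log2fc"], tab.loc[~sig, "delta_meth"], s=4,
               alpha=0.3, color="steelblue")
    ax.scatter(tab.loc[sig, "log2fc"], tab.loc[sig, "delta_meth"], s=8,
               color="red", label="differential")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    counts = diff_result.quadrant_counts
    ax.set_title("Q1..Q4 differential: " + "/".join(str(counts[q]) for q in (1, 2, 3, 4)),
                 fontsize=9)
    ax.set_xlabel("log2 fold change (A/B)")
    ax.set_ylabel("delta methylation (A-B)")
    ax.legend(fontsize=7)
    _finish(fig, path)


def heatmap_plot(result, path: str | Path) -> None:
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(6, max(3, 0.08 * len(result.order))),
        gridspec_kw={"width_ratios": [1, 3]},
    )
    hierarchy.dendrogram(result.linkage, orientation="left", ax=ax_d, no_labels=True)
    ax_d.axis("off")
    mat = result.matrix.loc[result.order[::-1]]
    ax_h.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax_h.set_xticks(range(mat.shape[1]), mat.columns, fontsize=7)
    ax_h.set_yticks([])
    _finish(fig, path)
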