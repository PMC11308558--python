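"""Report figures: combo plots (high-resolution histogram + box strip +
quantile rug), dendrograms and the correlation heatmap.

All functions write PNG files and return their paths; the report embeds them
by reference. Plotting is optional — every result is also available
numerically — so this module is only imported when plots are requested.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

from .bundle import ScreeningBundle
from .data_model import AnalysisDataset

__all__ = ["combo_plot", "dendrogram_plot", "heatmap_plot", "render_all_plots"]


def combo_plot(values: np.ndarray, title: str, path: Path, bins: int = 100) -> Path:
    """Histogram with box strip and data rug for one variable."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    fig, (ax_h, ax_b) = plt.subplots(
        2, 1, figsize=(6, 3.2), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.05})
    ax_h.hist(x, bins=bins, color="#4878a8")
    ax_h.set_title(title, fontsize=10)
    ax_b.boxplot(x, orientation="horizontal", widths=0.6, showfliers=False)
    ax_b.plot(x, np.full_like(x, 0.6), "|", color="black", alpha=0.2, markersize=4)
    ax_b.set_yticks([])
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def dendrogram_plot(dendro, title: str, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(dendro.leaves))))
    labels = [
        f"{leaf} ({100 * dendro.leaf_annotations[leaf]:.0f}%)"
        if leaf in dendro.leaf_annotations else leaf
        for leaf in dendro.leaves
    ]
    scipy_dendrogram(dendro.merge_matrix, labels=labels, orientation="right",
                     ax=ax, color_threshold=0)
    ax.set_title(title, fontsize=10)
    ax.tick_params(labelsize=7)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def heatmap_plot(matrix, title: str, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.variables)))
    ax.set_yticks(range(len(matrix.variables)))
    ax.set_xticklabels(matrix.variables, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.variables, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title, fontsize=10)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def render_all_plots(
    bundle: ScreeningBundle, ds: AnalysisDataset, out_dir: Path
) -> dict[str, str]:
    """Write the report figure set; returns {image key: relative path}."""
    img_dir = out_dir / "figures"
    img_dir.mkdir(exist_ok=True)
    images: dict[str, str] = {}

    # combo plots for the transformed-vs-raw showcase: variables with a
    # chosen transformation
    for dec in bundle.transform_decisions:
        if dec.chosen in ("pseudolog", "cuberoot"):
            x = ds.df[dec.variable].to_numpy(dtype=float)
            p = combo_plot(x, dec.variable, img_dir / f"combo_{dec.variable}.png")
            images[f"combo_{dec.variable}"] = str(p.relative_to(out_dir))

    if bundle.missingness_dendrogram is not None:
        p = dendrogram_plot(bundle.missingness_dendrogram,
                            "Missingness discordance",
                            img_dir / "missingness_dendrogram.png")
        images["missingness_dendrogram"] = str(p.relative_to(out_dir))
    if bundle.variable_dendrogram is not None:
        p = dendrogram_plot(bundle.variable_dendrogram,
                            "Variable clustering (1 - rho^2)",
                            img_dir / "variable_dendrogram.png")
        images["variable_dendrogram"] = str(p.relative_to(out_dir))
    if bundle.spearman is not None:
        p = heatmap_plot(bundle.spearman, "Spearman correlations",
                         img_dir / "correlation_heatmap.png")
        images["correlation_heatmap"] = str(p.relative_to(out_dir))
    return images
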