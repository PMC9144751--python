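"""Optional figure output: parallel-coordinates trait plot, metabolite
heatmap, PCA biplot.  All functions take the result objects computed by
the library and write a file; nothing here feeds back into analysis."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pbci import PBCIRecord, parallel_coordinates_table
from .stats import HeatmapResult, PCAResult
from .traits import TRAIT_NAMES

__all__ = ["plot_parallel_coordinates", "plot_heatmap", "plot_biplot"]

_PROMOTE = "#2166ac"  # blue: promoter / alleviator
_INDUCE = "#b2182b"   # red: inductor


def plot_parallel_coordinates(records: Sequence[PBCIRecord], path: str | Path) -> Path:
    """One panel per condition, one line per treatment across the five
    trait log2 ratios; blue = promoter/alleviator, red = inductor."""
    table = parallel_coordinates_table(records)
    conditions = list(dict.fromkeys(r.condition for r in records))
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(4 * len(conditions), 3.2), sharey=True
    )
    axes = np.atleast_1d(axes)
    xs = np.arange(len(TRAIT_NAMES))
    for ax, cond in zip(axes, conditions):
        sub = table[table["condition"] == cond]
        for (treat, conc), g in sub.groupby(["treatment", "concentration"]):
            if treat == "control":
                continue
            g = g.set_index("trait").reindex(TRAIT_NAMES)
            color = _INDUCE if g["label"].iloc[0] == "inductor" else _PROMOTE
            ax.plot(xs, g["log2_ratio"], marker="o", ms=3, color=color,
                    label=f"{conc:g} mM {treat}")
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_xticks(xs, TRAIT_NAMES, rotation=45)
        ax.set_title(cond)
    axes[0].set_ylabel("log2(treatment / control)")
    axes[-1].legend(fontsize=6, loc="best")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_heatmap(hm: HeatmapResult, path: str | Path) -> Path:
    """Class-blocked ln group-mean heatmap with post hoc dots."""
    fig, ax = plt.subplots(
        figsize=(0.45 * hm.values.shape[1] + 3, 0.22 * hm.values.shape[0] + 2)
    )
    im = ax.imshow(hm.values.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(hm.values.shape[1]), hm.values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(hm.values.shape[0]), hm.values.index, fontsize=6)
    if hm.significant is not None:
        ys, xs = np.nonzero(hm.significant.to_numpy())
        ax.scatter(xs, ys, s=6, c="black")
    fig.colorbar(im, ax=ax, label="ln(group mean)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_biplot(pca: PCAResult, path: str | Path, *, n_arrows: int = 15) -> Path:
    """Scores + strongest loadings on PC1/PC2 with variance fractions."""
    fig, ax = plt.subplots(figsize=(6, 5))
    s = pca.scores
    ax.scatter(s["PC1"], s["PC2"], s=18)
    for name, row in s.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=5)
    load = pca.loadings
    strength = (load["PC1"] ** 2 + load["PC2"] ** 2).nlargest(n_arrows).index
    scale = 0.8 * max(s["PC1"].abs().max(), s["PC2"].abs().max())
    for var in strength:
        ax.annotate(
            "", xy=(load.loc[var, "PC1"] * scale, load.loc[var, "PC2"] * scale),
            xytext=(0, 0), arrowprops=dict(arrowstyle="->", color="crimson", lw=0.8),
        )
        ax.annotate(var, (load.loc[var, "PC1"] * scale, load.loc[var, "PC2"] * scale),
                    fontsize=6, color="crimson")
    ve = pca.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.6)
    ax.axvline(0, color="0.8", lw=0.6)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
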