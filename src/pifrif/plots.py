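"""Optional figures: MA scatter, RIF1-vs-RIF2 scatter, panel heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def ma_plot(ma: pd.DataFrame, path: str | Path, title: str = "MA plot") -> None:
    """Scatter M against A, highlighting the flagged gene set."""
    fig, ax = plt.subplots(figsize=(6, 5))
    bg = ma[~ma["highlight"]]
    fg = ma[ma["highlight"]]
    ax.scatter(bg["a"], bg["m"], s=4, c="0.7", linewidths=0, rasterized=True)
    if len(fg):
        ax.scatter(fg["a"], fg["m"], s=8, c="crimson", linewidths=0)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("A (mean log2 abundance)")
    ax.set_ylabel("M (log2 HFE - LFE)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rif_scatter(rift: pd.DataFrame, path: str | Path) -> None:
    """RIF1 vs RIF2 z-scores with outliers labelled."""
    fig, ax = plt.subplots(figsize=(6, 5))
    normal = rift[~rift["outlier"]]
    out = rift[rift["outlier"]]
    ax.scatter(normal["rif1_z"], normal["rif2_z"], s=8, c="0.6", linewidths=0)
    ax.scatter(out["rif1_z"], out["rif2_z"], s=16, c="crimson", linewidths=0)
    for reg, row in out.iterrows():
        ax.annotate(str(reg), (row["rif1_z"], row["rif2_z"]), fontsize=7)
    ax.set_xlabel("RIF1 (z)")
    ax.set_ylabel("RIF2 (z)")
    ax.set_title("Differential connectivity of regulators")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def panel_heatmap(normed: pd.DataFrame, groups: pd.Series, path: str | Path) -> None:
    """Row-normalised panel expression, samples ordered by group."""
    order = groups.reindex(normed.columns).sort_values().index
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(normed[order], aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(np.arange(len(order)), labels=order, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(len(normed.index)), labels=normed.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.5, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
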