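"""Optional PNG outputs for visual inspection (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_pixelmap_png", "save_dccm_heatmap", "save_importance_heatmap"]


def save_pixelmap_png(image: np.ndarray, path, upscale: int = 8) -> None:
    """One conformation's pixel map, nearest-neighbour upscaled."""
    big = np.repeat(np.repeat(image, upscale, axis=0), upscale, axis=1)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(big, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_dccm_heatmap(matrix: np.ndarray, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=-1, vmax=1, origin="lower")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.colorbar(im, ax=ax, label=r"$C_{ij}$")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_importance_heatmap(table_df, path, top: int = 50) -> None:
    """Bar/heat strip of the top residues' importance scores."""
    df = table_df.sort_values("rank").head(top)
    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.bar(range(len(df)), df["score"], color="steelblue")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["residue"], rotation=90, fontsize=6)
    ax.set_ylabel("importance")
    ax.set_xlabel("residue (ranked)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
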