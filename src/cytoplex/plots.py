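"""Optional figure outputs: cell maps, positivity overlays, cutoff traces.

CSVs are the pipeline contract; these renderings support visual QC.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .positivity import CutoffResult  # noqa: E402


def cell_map(annotations: pd.DataFrame, image_id: str, path: str | Path,
             point_size: float = 4.0) -> None:
    """Scatter of cell centroids coloured by final label (one image)."""
    sub = annotations[annotations["image_id"] == image_id]
    fig, ax = plt.subplots(figsize=(7, 7))
    for lab, grp in sub.groupby("label", sort=True):
        ax.scatter(grp["x"], grp["y"], s=point_size, label=str(lab), linewidths=0)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"{image_id}: cell objects")
    ax.legend(markerscale=3, fontsize=7, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def positivity_overlay(cells_df: pd.DataFrame, cell_pos: pd.DataFrame,
                       marker: str, image_id: str, path: str | Path,
                       point_size: float = 4.0) -> None:
    """Positive cells for one marker highlighted over all centroids."""
    sel = (cells_df["image_id"] == image_id).to_numpy()
    pos = cell_pos[marker].to_numpy()[sel]
    x = cells_df.loc[sel, "x"]
    y = cells_df.loc[sel, "y"]
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(x[~pos], y[~pos], s=point_size, c="lightgray", linewidths=0)
    ax.scatter(x[pos], y[pos], s=point_size, c="crimson", linewidths=0,
               label=f"{marker}+ ({int(pos.sum())})")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title(f"{image_id}: {marker} positivity")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def cutoff_trace(result: CutoffResult, path: str | Path) -> None:
    """Rare/dominant ratio against the cutoff grid with the excluded band
    and the selected cutoff."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(result.cutoffs, result.ratio, lw=1)
    if result.excluded.any():
        ax.fill_between(result.cutoffs, 0, 1, where=result.excluded,
                        color="0.85", transform=ax.get_xaxis_transform(),
                        label="excluded (empty dominant)")
    ax.axvline(result.selected, color="k", lw=1.2,
               label=f"selected {result.selected:.4f}")
    ax.set_xlabel("D-score cutoff")
    ax.set_ylabel("rare / dominant cell ratio")
    ax.set_title(f"confidence group: {result.confidence}")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
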