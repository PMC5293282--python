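"""Visual summaries: kymographs, cell towers and summary figures.

Every figure-like product has a machine-readable twin (the array or table
it was drawn from), so figures are presentation only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .tracking import CellTrack  # noqa: E402

__all__ = ["kymograph", "cell_tower", "save_pie", "save_density",
           "save_pattern_bars"]


def kymograph(track: CellTrack, fluor_stack: np.ndarray,
              mask_stack: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Long-axis projection of in-mask fluorescence, one row per frame.

    Each frame's in-mask intensity is summed into ``n_bins`` relative
    long-axis position bins, so every row conserves that frame's total
    in-mask intensity exactly.
    """
    if track.n_frames == 0:
        raise ValueError("empty track")
    rows = []
    for trow in track.frames.itertuples():
        f = int(trow.frame)
        mask = mask_stack[f] == trow.label
        ys, xs = np.nonzero(mask)
        # relative long-axis coordinate of each mask pixel
        proj = ((xs - trow.cx) * trow.ax + (ys - trow.cy) * trow.ay)
        rel = proj / (proj.max() - proj.min() + 1e-9) + 0.5
        bins = np.clip((rel * n_bins).astype(int), 0, n_bins - 1)
        row = np.bincount(bins, weights=fluor_stack[f][ys, xs],
                          minlength=n_bins)
        rows.append(row)
    return np.vstack(rows)


def cell_tower(track: CellTrack, fluor_stack: np.ndarray,
               mask_stack: np.ndarray, pad: int = 2,
               separator: int = 1) -> np.ndarray:
    """Vertical montage of the cell's cropped images in temporal order."""
    if track.n_frames == 0:
        raise ValueError("empty track")
    strips = []
    for trow in track.frames.itertuples():
        f = int(trow.frame)
        mask = mask_stack[f] == trow.label
        ys, xs = np.nonzero(mask)
        y0, y1 = ys.min() - pad, ys.max() + pad + 1
        x0, x1 = xs.min() - pad, xs.max() + pad + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        strip = fluor_stack[f][y0:y1, x0:x1].astype(float)
        strips.append(strip)
    width = max(s.shape[1] for s in strips)
    height = max(s.shape[0] for s in strips)
    bg = min(float(s.min()) for s in strips)
    canvas = []
    for s in strips:
        padded = np.full((height, width), bg)
        oy = (height - s.shape[0]) // 2
        ox = (width - s.shape[1]) // 2
        padded[oy:oy + s.shape[0], ox:ox + s.shape[1]] = s
        canvas.append(padded)
        canvas.append(np.full((separator, width), bg))
    return np.vstack(canvas[:-1])


def save_pie(fraction_coloc: float, path) -> None:
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.pie([fraction_coloc, 1 - fraction_coloc],
           labels=[f"co-localized\n{100 * fraction_coloc:.0f}%",
                   f"resolved\n{100 * (1 - fraction_coloc):.0f}%"],
           colors=["#4878CF", "#D65F5F"], startangle=90)
    ax.set_title("sister fork pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_density(matrix: np.ndarray, pos_edges, length_edges, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, origin="lower", aspect="auto", cmap="inferno",
                   extent=(length_edges[0], length_edges[-1],
                           pos_edges[0], pos_edges[-1]))
    ax.set_xlabel("cell length (um)")
    ax.set_ylabel("relative long-axis position")
    fig.colorbar(im, ax=ax, label="P(position | length)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_pattern_bars(patterns: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    patterns["overall"].plot.bar(ax=ax, color="#4878CF")
    ax.set_ylabel("frequency")
    ax.set_title("cellular localization patterns")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
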