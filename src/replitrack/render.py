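"""Render simulated cells into fluorescence and label-mask image stacks.

Each founder lineage occupies one horizontal "lane" of the image.  Within a
lane, cells are laid out end to end along x (their long axis), pushing each
other apart as they elongate — the layout a microcolony constrained to a
narrow channel would adopt.  Cell masks are stadium-shaped (a rectangle with
semicircular caps); emitters are rendered as isotropic 2-D Gaussians of
width ``psf_sigma`` at sub-pixel positions, on a constant background, with
optional shot noise.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth, SimConfig

__all__ = ["render_frames", "RenderError"]

_GAP_PX = 3.0  # spacing between sibling cells in a lane


class RenderError(ValueError):
    pass


def _lane_layout(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Per-frame cell placement: left pole x, length (px) and lane center y."""
    px_per_um = 1000.0 / config.pixel_size_nm
    dt = config.frame_interval_min
    rows = []
    cells = truth.cells
    for frame in range(truth.n_frames):
        alive = cells[(cells.birth_frame <= frame)
                      & ((cells.division_frame < 0)
                         | (cells.division_frame > frame))]
        for lane, group in alive.groupby("lane"):
            group = group.sort_values("order")
            lengths = (group.birth_length_um
                       * np.exp((frame - group.birth_frame) * dt
                                / group.t0_min)).to_numpy() * px_per_um
            total = lengths.sum() + _GAP_PX * (len(group) - 1)
            x = (config.lane_width_px - total) / 2.0
            cy = lane * config.lane_height_px + config.lane_height_px / 2.0
            for cid, L in zip(group.cell_id.to_numpy(), lengths):
                rows.append((frame, int(cid), int(lane), x, L, cy))
                x += L + _GAP_PX
    return pd.DataFrame(
        rows, columns=["frame", "cell_id", "lane", "x0_px", "length_px",
                       "cy_px"])


def _stadium(canvas: np.ndarray, x0, cy, length_px, width_px, value):
    """Paint a stadium (rod) mask with the given label value."""
    r = width_px / 2.0
    cx = x0 + length_px / 2.0
    h = max(length_px / 2.0 - r, 0.0)
    xlo = max(int(math.floor(x0)) - 1, 0)
    xhi = min(int(math.ceil(x0 + length_px)) + 1, canvas.shape[1])
    ylo = max(int(math.floor(cy - r)) - 1, 0)
    yhi = min(int(math.ceil(cy + r)) + 1, canvas.shape[0])
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    dx = np.clip(np.abs(xx - cx) - h, 0.0, None)
    inside = dx ** 2 + (yy - cy) ** 2 <= r * r
    canvas[ylo:yhi, xlo:xhi][inside] = value


def _splat(canvas: np.ndarray, ex, ey, amp, sigma_px):
    w = int(math.ceil(6 * sigma_px))
    xlo, xhi = max(int(ex) - w, 0), min(int(ex) + w + 1, canvas.shape[1])
    ylo, yhi = max(int(ey) - w, 0), min(int(ey) + w + 1, canvas.shape[0])
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    canvas[ylo:yhi, xlo:xhi] += amp * np.exp(
        -((xx - ex) ** 2 + (yy - ey) ** 2) / (2 * sigma_px ** 2))


def render_frames(truth: GroundTruth, config: SimConfig | None = None,
                  out_dir=None):
    """Render a :class:`GroundTruth` into image stacks.

    Returns ``(fluor, masks, layout)`` where ``fluor`` and ``masks`` are
    uint16 arrays of shape (frames, height, width) and ``layout`` is the
    per-frame cell placement table.  If ``out_dir`` is given, writes
    ``fluor.tif``, ``masks.tif``, ``layout.csv`` and the ground-truth
    sidecars (JSON + CSV) there.

    Mask labels are ``cell_id + 1`` and therefore stable across frames; a
    division retires the parent label and issues two new ones.
    """
    if config is None:
        config = truth.config
    config.validate()
    n_lanes = int(truth.cells.lane.max()) + 1
    shape = (n_lanes * config.lane_height_px, config.lane_width_px)
    if config.image_shape is not None:
        if (config.image_shape[0] < shape[0]
                or config.image_shape[1] < shape[1]):
            raise RenderError(
                f"image_shape {config.image_shape} too small for "
                f"{n_lanes} lanes of {config.lane_height_px}px x "
                f"{config.lane_width_px}px")
        shape = tuple(config.image_shape)

    layout = _lane_layout(truth, config)
    px_per_um = 1000.0 / config.pixel_size_nm
    sigma_px = config.psf_sigma_nm / config.pixel_size_nm
    width_px = config.cell_width_um * px_per_um
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))

    fluor = np.empty((truth.n_frames, *shape), dtype=np.uint16)
    masks = np.zeros((truth.n_frames, *shape), dtype=np.uint16)
    emitters = truth.emitters
    em_by_frame = dict(tuple(emitters.groupby("frame"))) if len(emitters) else {}
    lay_by_frame = dict(tuple(layout.groupby("frame")))

    for frame in range(truth.n_frames):
        lay = lay_by_frame.get(frame)
        canvas = np.full(shape, float(config.background_level))
        mask = masks[frame]
        placement = {}
        if lay is not None:
            for row in lay.itertuples():
                if row.x0_px < 1 or row.x0_px + row.length_px > shape[1] - 1:
                    raise RenderError(
                        f"cell {row.cell_id} exceeds lane width at frame "
                        f"{frame}; increase lane_width_px or shorten the run")
                _stadium(mask, row.x0_px, row.cy_px, row.length_px, width_px,
                         row.cell_id + 1)
                placement[row.cell_id] = row
        ems = em_by_frame.get(frame)
        if ems is not None:
            for em in ems.itertuples():
                p = placement.get(em.cell_id)
                if p is None:
                    raise RenderError(
                        f"emitter of pair {em.pair_id} references cell "
                        f"{em.cell_id} absent at frame {frame}")
                ex = p.x0_px + em.x_rel * p.length_px
                ey = p.cy_px + (em.y_rel - 0.5) * width_px * 0.5
                if not (0 <= ex < shape[1] and 0 <= ey < shape[0]):
                    raise RenderError(
                        f"emitter outside image bounds: cell {em.cell_id}, "
                        f"frame {frame}, x={ex:.1f}, y={ey:.1f}")
                amp = config.focus_amplitude * em.brightness
                if config.amplitude_cv > 0:
                    amp *= rng.lognormal(0.0, config.amplitude_cv)
                _splat(canvas, ex, ey, amp, sigma_px)
        if config.noise_model == "poisson":
            canvas = rng.poisson(canvas).astype(float)
        elif config.noise_model == "gaussian":
            canvas = canvas + rng.normal(0.0, config.noise_sd, size=shape)
        fluor[frame] = np.clip(np.round(canvas), 0, 65535).astype(np.uint16)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "fluor.tif", fluor, photometric="minisblack")
        tifffile.imwrite(out / "masks.tif", masks, photometric="minisblack")
        layout.to_csv(out / "layout.csv", index=False)
        truth.save(out)
    return fluor, masks, layout
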