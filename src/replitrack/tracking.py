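"""Cell tracks, long-axis geometry, exponential growth fits and selection.

Input is a label-mask stack in which each cell keeps one integer label for
its whole life and a division retires the parent label, issuing two fresh
labels.  Tracks carry per-frame length (maximal Feret extent along the
mask's principal axis), centroid and long-axis direction; lineage links are
inferred from pixel overlap between a retired label and the labels that
appear in its place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.measure import regionprops

__all__ = [
    "CellTrack",
    "GrowthFit",
    "build_tracks",
    "long_axis_position",
    "fit_growth",
    "select_cells",
]

LN2 = math.log(2.0)

# selection windows (spec'd by the analysis protocol)
DOUBLING_TIME_WINDOW_H = (1.5, 4.5)
BIRTH_LENGTH_WINDOW_UM = (1.0, 4.0)
# in snapshot mode birth length is unobservable; the observed length may lie
# anywhere between birth and division, so the window is stretched by one
# doubling at the top end
SNAPSHOT_LENGTH_WINDOW_UM = (1.0, 8.0)

MAX_LENGTH_JUMP = 0.20  # fractional length change per frame flagged as error


@dataclass
class CellTrack:
    """One cell from (observed) birth to division.

    ``frames`` columns: frame, label, length_um, cx, cy (centroid, px),
    ax, ay (long-axis unit vector, pole-stable sign).
    """

    cell_id: int
    frames: pd.DataFrame
    parent_id: int = -1
    daughter_ids: tuple = ()
    flags: frozenset = field(default_factory=frozenset)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def birth_length_um(self) -> float:
        return float(self.frames.length_um.iloc[0])

    @property
    def division_length_um(self) -> float:
        return float(self.frames.length_um.iloc[-1])

    @property
    def complete_cycle(self) -> bool:
        """Both bounding divisions observed."""
        return self.parent_id >= 0 and len(self.daughter_ids) == 2

    @property
    def has_error(self) -> bool:
        return bool(self.flags)


@dataclass
class GrowthFit:
    """Exponential elongation fit L(t) = L0 * exp(t / t0)."""

    cell_id: int
    L0_um: float
    t0_min: float
    rss: float
    ok: bool

    @property
    def tD_min(self) -> float:
        """Doubling time tD = t0 * ln 2."""
        return self.t0_min * LN2


def _frame_geometry(mask: np.ndarray, pixel_size_nm: float):
    """label -> (length_um, cx, cy, ax, ay) for one label frame."""
    out = {}
    px_um = pixel_size_nm / 1000.0
    for prop in regionprops(mask):
        theta = prop.orientation  # angle between y-axis (rows) and major axis
        # unit vector of the major axis in (x, y) = (col, row) coordinates
        ax, ay = math.sin(theta), math.cos(theta)
        coords = prop.coords  # (row, col)
        proj = coords[:, 1] * ax + coords[:, 0] * ay
        length_um = (proj.max() - proj.min() + 1.0) * px_um
        cy, cx = prop.centroid
        out[prop.label] = (length_um, cx, cy, ax, ay)
    return out


def build_tracks(mask_stack: np.ndarray,
                 pixel_size_nm: float = 160.0) -> dict[int, CellTrack]:
    """Build one :class:`CellTrack` per label of a label-mask stack.

    Lineage is inferred from label turnover: when a label disappears and two
    new labels appear on its former pixels, the new labels are recorded as
    daughters.  A label that vanishes and later reappears is flagged as a
    segmentation error, as are implausible (>20 %/frame) length jumps.
    """
    n_frames = mask_stack.shape[0]
    rows: dict[int, list] = {}
    present: dict[int, list] = {}
    geom_prev: dict[int, tuple] = {}
    for f in range(n_frames):
        geom = _frame_geometry(mask_stack[f], pixel_size_nm)
        for label, (length, cx, cy, ax, ay) in geom.items():
            prev = geom_prev.get(label)
            if prev is not None:
                # keep the pole identity: axis sign follows the previous frame
                if ax * prev[3] + ay * prev[4] < 0:
                    ax, ay = -ax, -ay
                    geom[label] = (length, cx, cy, ax, ay)
            rows.setdefault(label, []).append(
                (f, label, length, cx, cy, ax, ay))
            present.setdefault(label, []).append(f)
        geom_prev = geom

    # lineage: for every label ending at frame f, daughters are the labels
    # starting at f whose pixels overlap the parent's last mask
    starts = {lab: fr[0] for lab, fr in present.items()}
    ends = {lab: fr[-1] for lab, fr in present.items()}
    parent_of: dict[int, int] = {}
    daughters_of: dict[int, list] = {}
    for lab, end in ends.items():
        if end + 1 >= n_frames:
            continue
        prev_mask = mask_stack[end] == lab
        nxt = mask_stack[end + 1]
        cand = np.unique(nxt[prev_mask])
        kids = [int(c) for c in cand
                if c != 0 and c != lab and starts.get(int(c)) == end + 1]
        if len(kids) == 2:
            daughters_of[lab] = kids
            for k in kids:
                parent_of[k] = lab

    tracks: dict[int, CellTrack] = {}
    for lab, rlist in rows.items():
        df = pd.DataFrame(
            rlist, columns=["frame", "label", "length_um", "cx", "cy",
                            "ax", "ay"])
        flags = set()
        fr = df.frame.to_numpy()
        if np.any(np.diff(fr) != 1):
            flags.add("gap")
        lens = df.length_um.to_numpy()
        if len(lens) > 1:
            rel = np.abs(np.diff(lens)) / lens[:-1]
            if np.any(rel > MAX_LENGTH_JUMP):
                flags.add("length_jump")
        tracks[lab] = CellTrack(
            cell_id=int(lab), frames=df,
            parent_id=int(parent_of.get(lab, -1)),
            daughter_ids=tuple(daughters_of.get(lab, ())),
            flags=frozenset(flags))
    return tracks


def long_axis_position(focus_xy, track_frame, pixel_size_nm: float = 160.0,
                       length_um: float | None = None) -> float:
    """Relative long-axis coordinate of a point inside a cell.

    0.5 is midcell; 0 and 1 are the poles (sign anchored by the track's
    pole-stable axis convention).  ``track_frame`` is a row of
    ``CellTrack.frames``.
    """
    x, y = focus_xy
    L = length_um if length_um is not None else track_frame.length_um
    proj_um = ((x - track_frame.cx) * track_frame.ax
               + (y - track_frame.cy) * track_frame.ay) * pixel_size_nm / 1000.0
    rel = proj_um / L + 0.5
    slack = (pixel_size_nm / 1000.0) / L  # one pixel of tolerance at the poles
    if rel < -slack or rel > 1 + slack:
        raise ValueError(
            f"focus at ({x:.1f}, {y:.1f}) projects outside the cell "
            f"(rel={rel:.3f})")
    return float(np.clip(rel, 0.0, 1.0))


def fit_growth(track: CellTrack,
               frame_interval_min: float = 5.0) -> GrowthFit:
    """Least-squares exponential fit of the length-vs-time curve.

    Fits L(t) = L0 * exp(t / t0) in linear length space with L0 and t0 free;
    the doubling time is tD = t0 * ln 2.  Cells whose fit does not converge,
    or converges to a non-elongating solution (t0 <= 0 or absurdly large),
    are flagged and excluded downstream.
    """
    if track.n_frames < 4:
        return GrowthFit(track.cell_id, math.nan, math.nan, math.nan, False)
    t = (track.frames.frame.to_numpy()
         - track.frames.frame.iloc[0]) * frame_interval_min
    L = track.frames.length_um.to_numpy()
    if np.any(L <= 0):
        return GrowthFit(track.cell_id, math.nan, math.nan, math.nan, False)
    # log-linear regression for the starting point
    slope, icept = np.polyfit(t, np.log(L), 1)
    if slope <= 1e-6:
        return GrowthFit(track.cell_id, math.nan, math.nan, math.nan, False)
    try:
        popt, _ = curve_fit(
            lambda tt, L0, t0: L0 * np.exp(tt / t0), t, L,
            p0=(math.exp(icept), 1.0 / slope), maxfev=10000)
    except RuntimeError:
        return GrowthFit(track.cell_id, math.nan, math.nan, math.nan, False)
    L0, t0 = float(popt[0]), float(popt[1])
    rss = float(np.sum((L0 * np.exp(t / t0) - L) ** 2))
    ok = 0.0 < t0 < 1e5 and L0 > 0
    return GrowthFit(track.cell_id, L0, t0, rss, ok)


def select_cells(tracks: dict[int, CellTrack],
                 fits: dict[int, GrowthFit] | None = None,
                 mode: str = "timelapse") -> dict[int, CellTrack]:
    """Apply the automated selection filters; no manual curation.

    Timelapse: (i) no segmentation-error flag, (ii) doubling time between
    1.5 and 4.5 h, (iii) birth length 1-4 um.  Snapshot: criterion (ii)
    cannot be evaluated and is skipped; the length window is widened to one
    doubling above the birth window since cell age is unknown.
    """
    if mode not in ("timelapse", "snapshot"):
        raise ValueError(f"mode must be timelapse or snapshot, got {mode!r}")
    selected = {}
    for cid, tr in tracks.items():
        if tr.has_error:
            continue
        if mode == "timelapse":
            if fits is None or cid not in fits:
                continue
            fit = fits[cid]
            if not fit.ok:
                continue
            tD_h = fit.tD_min / 60.0
            if not (DOUBLING_TIME_WINDOW_H[0] <= tD_h
                    <= DOUBLING_TIME_WINDOW_H[1]):
                continue
            lo, hi = BIRTH_LENGTH_WINDOW_UM
            if not (lo <= tr.birth_length_um <= hi):
                continue
        else:
            lo, hi = SNAPSHOT_LENGTH_WINDOW_UM
            if not (lo <= tr.birth_length_um <= hi):
                continue
        selected[cid] = tr
    return selected
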