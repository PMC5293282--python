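"""Focus detection, sub-pixel Gaussian localization and significance scoring.

The detection chain per frame:

1. a small Gaussian blur of the fluorescence image;
2. a watershed of the conjugate (inverted) blurred image, seeded at its
   regional maxima, partitioning the frame into intensity regions;
3. regions outside the cell masks are discarded; each remaining region
   yields one candidate at its maximum-intensity pixel;
4. a 2-D Gaussian ``Ig * exp(-|x - x0|^2 / (2 b^2)) + I0`` is least-squares
   fitted to the raw image over a small disk around the candidate; the
   fitted x0 is the focus position used for all localization;
5. the focus significance score is computed from disk photometry:
   ``sigma = Ia / (deltaI * sqrt(A))`` where ``Ia`` is the
   background-subtracted intensity summed over a disk of A pixels centered
   at the fitted position (background = minimum disk pixel times A) and
   ``deltaI`` is the intensity standard deviation over the entire cell
   mask.  Foci scoring at or above the threshold are retained.

Disk sums are measured on the blurred image — the same image the watershed
sees; this is what makes the min-pixel background estimator usable, since
on the raw image shot noise alone biases the disk sum far above the
minimum-pixel baseline.  ``deltaI`` is taken on the raw image.
Detection contains no randomness: identical inputs give identical foci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .tracking import CellTrack, long_axis_position

__all__ = [
    "DetectionParams",
    "Focus",
    "drift_correct",
    "detect_candidates",
    "fit_focus",
    "score_focus",
    "detect_foci",
    "disk_offsets",
]


@dataclass(frozen=True)
class DetectionParams:
    blur_sigma: float = 1.25       # px; width of the detection blur
    disk_radius: int = 3           # px; photometry disk radius
    score_threshold: float = 4.0   # retention cutoff on sigma
    min_peak_distance: int = 2     # px; closer maxima merge into one candidate
    prefilter_score: float = 3.0   # provisional-score cutoff before fitting

    @property
    def disk_area(self) -> int:
        """Number of pixels in the discrete disk (29 for radius 3)."""
        return len(disk_offsets(self.disk_radius))

    def validate(self):
        if self.disk_radius < 1:
            raise ValueError("disk_radius must be >= 1")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")


@dataclass
class Focus:
    """One candidate or retained focus."""

    cell_id: int
    frame: int
    x0: float                    # sub-pixel position (px)
    y0: float
    Ig: float                    # fitted Gaussian amplitude
    b: float                     # fitted Gaussian width (px)
    I0: float                    # fitted local background
    Ia: float = math.nan         # background-subtracted disk intensity
    Ib: float = math.nan         # min disk pixel * disk area
    score: float = math.nan
    retained: bool = False
    rel_pos: float = math.nan    # relative long-axis coordinate


_DISK_CACHE: dict[int, np.ndarray] = {}


def disk_offsets(radius: int) -> np.ndarray:
    """(dy, dx) offsets of pixels whose centers lie within ``radius``."""
    if radius not in _DISK_CACHE:
        r = int(radius)
        offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
                if dx * dx + dy * dy <= radius * radius]
        _DISK_CACHE[radius] = np.array(offs, dtype=int)
    return _DISK_CACHE[radius]


def drift_correct(frame_t: np.ndarray, frame_prev: np.ndarray,
                  max_shift: int | None = None) -> tuple[int, int]:
    """Integer-pixel (dy, dx) drift of ``frame_t`` relative to ``frame_prev``.

    The offset maximizes the cross-correlation between the two frames;
    shifting frame t (and its mask/fluorescence channels) back by this
    amount aligns it with the previous frame.  A correlation peak at the
    border is clamped with a warning.
    """
    if frame_t.shape != frame_prev.shape:
        raise ValueError("frames must have the same shape")
    shift, _, _ = phase_cross_correlation(
        frame_t.astype(float), frame_prev.astype(float), upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    limit = max_shift if max_shift is not None else min(frame_t.shape) // 4
    if abs(dy) > limit or abs(dx) > limit:
        warnings.warn(
            f"drift estimate ({dy}, {dx}) at/beyond the search border; "
            f"clamping to +/-{limit}", stacklevel=2)
        dy = int(np.clip(dy, -limit, limit))
        dx = int(np.clip(dx, -limit, limit))
    return dy, dx


def detect_candidates(fluor: np.ndarray, masks: np.ndarray,
                      params: DetectionParams | None = None):
    """Candidate foci of one frame.

    Returns ``(candidates, blurred)`` where candidates is a list of
    ``(y, x, cell_label)`` seeds, one per in-mask intensity region of the
    watershed of the conjugate blurred image.
    """
    params = params or DetectionParams()
    params.validate()
    blurred = gaussian_filter(fluor.astype(float), params.blur_sigma)
    if masks.max() == 0:
        return [], blurred
    inmask = masks > 0
    if np.ptp(blurred[inmask]) == 0:  # flat image: no intensity maxima
        return [], blurred
    r = params.disk_radius
    peaks = peak_local_max(
        blurred, min_distance=params.min_peak_distance,
        exclude_border=r, labels=inmask)
    if len(peaks) == 0:
        return [], blurred
    # watershed of the conjugate image partitions each cell into regions
    # around the surviving maxima; each region's seed is its max pixel
    markers = np.zeros(fluor.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    regions = watershed(-blurred, markers=markers, mask=inmask)
    candidates = []
    for i, (py, px) in enumerate(peaks):
        if regions[py, px] != i + 1:
            continue
        label = int(masks[py, px])
        if label > 0:
            candidates.append((int(py), int(px), label))
    return candidates, blurred


def _provisional_score(blurred, raw_std, py, px, params) -> float:
    offs = disk_offsets(params.disk_radius)
    vals = blurred[py + offs[:, 0], px + offs[:, 1]]
    Ia = vals.sum() - vals.min() * len(vals)
    A = len(vals)
    return float(Ia / (raw_std * math.sqrt(A))) if raw_std > 0 else 0.0


def fit_focus(fluor: np.ndarray, candidate, params: DetectionParams | None = None,
              frame: int = 0) -> Focus | None:
    """Least-squares Gaussian fit over the disk around a candidate.

    Fits on the *raw* image so the recovered width b reflects the optical
    spot size.  Returns None when the fit fails (degenerate candidates).
    """
    params = params or DetectionParams()
    py, px, label = candidate
    r = params.disk_radius
    if not (r <= px < fluor.shape[1] - r and r <= py < fluor.shape[0] - r):
        return None
    offs = disk_offsets(r)
    ys, xs = py + offs[:, 0], px + offs[:, 1]
    vals = fluor[ys, xs].astype(float)
    lo = float(vals.min())
    amp0 = max(float(vals.max()) - lo, 1e-6)

    def resid(p):
        Ig, x0, y0, b, I0 = p
        return Ig * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2)
                           / (2 * b * b)) + I0 - vals

    try:
        res = least_squares(
            resid, x0=np.array([amp0, px, py, 1.2, lo]),
            bounds=(np.array([0.0, px - r, py - r, 0.5, -np.inf]),
                    np.array([np.inf, px + r, py + r, 5.0, np.inf])),
            method="trf", xtol=1e-8, ftol=1e-8, max_nfev=100)
    except ValueError:
        return None
    if not res.success and res.status <= 0:
        return None
    Ig, x0, y0, b, I0 = (float(v) for v in res.x)
    return Focus(cell_id=label, frame=frame, x0=x0, y0=y0, Ig=Ig, b=b, I0=I0)


def score_focus(blurred: np.ndarray, focus: Focus, delta_I: float,
                params: DetectionParams | None = None) -> Focus:
    """Score a fitted focus and decide retention.

    The disk is centered on the pixel nearest the fitted position; the
    background is the minimum disk pixel times the disk area A; the score is
    ``Ia / (deltaI * sqrt(A))`` and the focus is retained iff it reaches the
    threshold.  A flat cell (deltaI = 0) scores 0 and is rejected.
    """
    params = params or DetectionParams()
    r = params.disk_radius
    py, px = int(round(focus.y0)), int(round(focus.x0))
    py = int(np.clip(py, r, blurred.shape[0] - r - 1))
    px = int(np.clip(px, r, blurred.shape[1] - r - 1))
    offs = disk_offsets(r)
    vals = blurred[py + offs[:, 0], px + offs[:, 1]].astype(float)
    A = len(vals)
    Ib = float(vals.min()) * A
    Ia = float(vals.sum()) - Ib
    if delta_I > 0:
        score = Ia / (delta_I * math.sqrt(A))
    else:
        score = 0.0
    focus.Ia, focus.Ib, focus.score = Ia, Ib, float(score)
    focus.retained = bool(score >= params.score_threshold)
    return focus


def detect_foci(fluor_stack: np.ndarray, mask_stack: np.ndarray,
                tracks: dict[int, CellTrack] | None = None,
                params: DetectionParams | None = None,
                pixel_size_nm: float = 160.0,
                keep_rejected: bool = False) -> pd.DataFrame:
    """Run the full detection chain over a stack; fully automated.

    Returns a tidy table (frame, cell_id, x0, y0, Ig, b, I0, Ia, Ib, score,
    retained, rel_pos, length_um).  ``rel_pos`` is filled from the track
    geometry when ``tracks`` is given.  Rejected candidates are dropped
    unless ``keep_rejected`` is set.
    """
    params = params or DetectionParams()
    params.validate()
    frame_rows = []
    track_frames = {}
    if tracks:
        for cid, tr in tracks.items():
            for row in tr.frames.itertuples():
                track_frames[(row.frame, cid)] = row
    offs = disk_offsets(params.disk_radius)
    sqrtA = math.sqrt(len(offs))
    for f in range(fluor_stack.shape[0]):
        raw = fluor_stack[f].astype(float)
        masks = mask_stack[f]
        blurred = gaussian_filter(raw, params.blur_sigma)
        inmask = masks > 0
        if not inmask.any() or np.ptp(blurred[inmask]) == 0:
            continue
        peaks = peak_local_max(
            blurred, min_distance=params.min_peak_distance,
            exclude_border=params.disk_radius, labels=inmask)
        if len(peaks) == 0:
            continue
        pys, pxs = peaks[:, 0], peaks[:, 1]
        cand_labels = masks[pys, pxs]
        # deltaI per cell: raw-intensity standard deviation over the mask
        labels = np.unique(cand_labels)
        with np.errstate(invalid="ignore", divide="ignore"):
            dI_arr = ndi.standard_deviation(raw, masks, index=labels)
        dI = dict(zip(labels.tolist(), np.atleast_1d(dI_arr).tolist()))
        # vectorized provisional score at the candidate pixel; candidates
        # that cannot approach the threshold are not worth a Gaussian fit
        vals = blurred[pys[:, None] + offs[:, 0], pxs[:, None] + offs[:, 1]]
        Ia_prov = vals.sum(axis=1) - vals.min(axis=1) * len(offs)
        dI_vec = np.array([dI[lab] for lab in cand_labels.tolist()])
        with np.errstate(divide="ignore", invalid="ignore"):
            prov = np.where(dI_vec > 0, Ia_prov / (dI_vec * sqrtA), 0.0)
        keep = prov >= params.prefilter_score
        for py, px, label in zip(pys[keep], pxs[keep], cand_labels[keep]):
            py, px, label = int(py), int(px), int(label)
            cand = (py, px, label)
            focus = fit_focus(raw, cand, params, frame=f)
            if focus is None:
                continue
            # the fitted position must stay inside the candidate's cell
            fy, fx = int(round(focus.y0)), int(round(focus.x0))
            if not (0 <= fy < masks.shape[0] and 0 <= fx < masks.shape[1]):
                continue
            if masks[fy, fx] != label:
                continue
            focus = score_focus(blurred, focus, dI[label], params)
            if not (focus.retained or keep_rejected):
                continue
            trow = track_frames.get((f, label))
            if trow is not None:
                try:
                    focus.rel_pos = long_axis_position(
                        (focus.x0, focus.y0), trow, pixel_size_nm)
                except ValueError:
                    continue
                length = trow.length_um
            elif tracks is not None:
                continue  # focus in a cell excluded from the analysis
            else:
                length = math.nan
            frame_rows.append((f, label, focus.x0, focus.y0, focus.Ig,
                               focus.b, focus.I0, focus.Ia, focus.Ib,
                               focus.score, focus.retained, focus.rel_pos,
                               length))
    return pd.DataFrame(
        frame_rows,
        columns=["frame", "cell_id", "x0", "y0", "Ig", "b", "I0", "Ia",
                 "Ib", "score", "retained", "rel_pos", "length_um"])
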