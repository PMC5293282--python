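"""Factory-model replisome simulator.

Simulates populations of exponentially elongating, dividing rod-shaped cells
in which pairs of sister replication forks behave as a mostly co-localized
"replication factory": a fork pair appears near midcell at initiation,
executes confined random motion, transiently fissions into two resolvable
sister foci, fuses again, and disassembles at termination.  In a fraction of
cycles the next round of replication initiates before division, producing a
pair of factories at the quarter-cell positions that persist through
division into the two daughters.

Positions are stored in *relative long-axis coordinates*: 0 and 1 are the
cell poles, 0.5 is midcell.  Rendering into images is done separately (see
:mod:`replitrack.render`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "preset",
    "simulate_population",
    "PRESET_NAMES",
]


@dataclass
class SimConfig:
    """Parameters of the cell-cycle / replisome simulation.

    Times are minutes, lengths micrometers unless the name says otherwise.
    """

    # imaging / rendering geometry
    frame_interval_min: float = 5.0
    pixel_size_nm: float = 110.0
    psf_sigma_nm: float = 160.0
    image_shape: tuple | None = None      # None -> derived from lane layout
    lane_height_px: int = 24
    lane_width_px: int = 176
    cell_width_um: float = 1.2

    # growth and division
    birth_length_mean_um: float = 3.5
    birth_length_sd_um: float = 0.3
    t0_mean_min: float = 260.0            # elongation time constant; tD = t0*ln2
    t0_sd_min: float = 25.0
    division_length_factor: float = 2.0   # divide when L >= factor * birth length
    division_length_noise_sd: float = 0.10  # lognormal noise on the threshold
    division_asymmetry_sd: float = 0.02   # relative length asymmetry of daughters

    # replication cycle
    replication_duration_mean_min: float = 135.0
    replication_duration_sd_min: float = 15.0
    d_period_mean_min: float = 12.0       # post-division gap before initiation
    d_period_sd_min: float = 5.0
    p_preinit: float = 0.45               # P(re-initiation precedes division)
    reinit_length_sd: float = 0.05        # lognormal sd of the re-init length
    reinit_enabled: bool = True
    reinit_positions: tuple = (0.275, 0.725)

    # fork-pair fission/fusion dynamics
    p_resolved: float = 0.20              # stationary P(resolved) for midcell pairs
    quarter_resolved_factor: float = 0.25  # quarter factories resolve more rarely
    resolved_sep_mean: float = 0.20       # relative cell lengths
    resolved_sep_sd: float = 0.045
    resolved_dwell_frames: float = 3.0    # mean length of a resolved episode
    confinement_sd: float = 0.02          # AR(1) amplitude of factory motion
    confinement_rho: float = 0.7          # AR(1) frame-to-frame correlation

    # photometry
    focus_amplitude: float = 2000.0       # peak photons of a co-localized pair
    amplitude_cv: float = 0.05            # lognormal frame-to-frame brightness jitter
    background_level: float = 100.0       # photons per pixel
    noise_model: str = "poisson"          # poisson | gaussian | none
    noise_sd: float = 10.0                # used by the gaussian model

    snapshot: bool = False                # one frame per independent cell
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_preinit", "p_resolved", "quarter_resolved_factor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        nonneg = (
            "frame_interval_min pixel_size_nm psf_sigma_nm birth_length_mean_um "
            "birth_length_sd_um t0_mean_min t0_sd_min replication_duration_mean_min "
            "replication_duration_sd_min d_period_mean_min d_period_sd_min "
            "resolved_sep_mean resolved_sep_sd confinement_sd focus_amplitude "
            "background_level noise_sd amplitude_cv"
        ).split()
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.resolved_sep_mean + 2 * self.resolved_sep_sd >= 0.33:
            raise ValueError(
                "resolved_sep_mean + 2*resolved_sep_sd must stay below 0.33 "
                "cell lengths (resolved sisters remain well inside the quarter "
                "positions)"
            )
        if self.psf_sigma_nm / self.pixel_size_nm < 0.5:
            raise ValueError("psf_sigma must be at least half a pixel to render")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape) if self.image_shape else None
        d["reinit_positions"] = list(self.reinit_positions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("image_shape"):
            d["image_shape"] = tuple(d["image_shape"])
        d["reinit_positions"] = tuple(d.get("reinit_positions", (0.275, 0.725)))
        return cls(**d)


# Stationary resolved-state probabilities are calibrated so that the
# time-averaged ground-truth co-localized fraction of fork-pair observations
# matches the published values (0.82 E. coli DnaN, 0.79 B. subtilis DnaN),
# accounting for the rarer fission of quarter-cell factories.
_PRESETS = {
    "ecoli_dnaN": dict(p_resolved=0.188),
    "bsubtilis_dnaN": dict(
        p_resolved=0.218,
        d_period_mean_min=30.0,
        division_length_noise_sd=0.13,
    ),
    "snapshot_marker": dict(p_resolved=0.20, snapshot=True),
    "reinit_blocked": dict(p_resolved=0.20, reinit_enabled=False),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> SimConfig:
    """Return a fully populated :class:`SimConfig` for a named condition."""
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Simulator truth: per-cell cycle events and per-frame emitter positions.

    ``cells`` columns: cell_id, parent_id (-1 for founders), lane, order,
    birth_frame, division_frame (-1 if division not reached), birth_length_um,
    division_length_um, t0_min, init_frame, term_frame, reinit_frame (-1 if
    re-initiation did not precede division), preinit (bool), complete (bool,
    division observed within the simulated window).

    ``emitters`` columns: frame, cell_id, pair_id, state
    ('colocalized'|'resolved'), x_rel, y_rel, brightness.  A co-localized
    pair contributes one emitter row per frame, a resolved pair two.
    """

    cells: pd.DataFrame
    emitters: pd.DataFrame
    config: SimConfig
    n_frames: int

    def cell_length_um(self, cell_id: int, frame: int) -> float:
        row = self.cells.loc[self.cells.cell_id == cell_id].iloc[0]
        dt = (frame - row.birth_frame) * self.config.frame_interval_min
        return float(row.birth_length_um * math.exp(dt / row.t0_min))

    def pair_state_counts(self) -> pd.DataFrame:
        """Per-frame number of fork pairs in each state."""
        one = self.emitters.drop_duplicates(["frame", "pair_id"])
        tab = (
            one.groupby(["frame", "state"]).size().unstack(fill_value=0)
            .reindex(columns=["colocalized", "resolved"], fill_value=0)
            .reset_index()
        )
        tab.columns = ["frame", "n_colocalized", "n_resolved"]
        return tab

    def preinit_frequency(self) -> tuple:
        """(fraction, n) of completed founder cycles with pre-division
        re-initiation.

        Later generations are censored toward fast cycles inside a finite
        observation window; founder cycles are covered completely, so the
        census uses them.
        """
        cyc = self.cells[(self.cells.parent_id < 0)
                         & (self.cells.division_frame >= 0)]
        if len(cyc) == 0:
            return float("nan"), 0
        return float(cyc.preinit.mean()), int(len(cyc))

    def colocalized_fraction(self) -> float:
        """Ground-truth fraction of fork-pair observations that are co-localized."""
        one = self.emitters.drop_duplicates(["frame", "pair_id"])
        return float((one.state == "colocalized").mean())

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "truth_cells.csv", index=False)
        self.emitters.to_csv(out / "truth_emitters.csv", index=False)
        meta = {
            "config": self.config.to_dict(),
            "n_frames": self.n_frames,
            "n_cells": int(len(self.cells)),
            "seed": self.config.seed,
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "GroundTruth":
        p = Path(in_dir)
        meta = json.loads((p / "truth.json").read_text())
        return cls(
            cells=pd.read_csv(p / "truth_cells.csv"),
            emitters=pd.read_csv(p / "truth_emitters.csv"),
            config=SimConfig.from_dict(meta["config"]),
            n_frames=int(meta["n_frames"]),
        )


@dataclass
class _Cell:
    cell_id: int
    parent_id: int
    lane: int
    order: str            # lexicographic left-to-right position within the lane
    birth_t: float
    L0: float
    t0: float
    div_len: float        # division length threshold
    birth_frame: int = 0
    division_frame: int = -1
    div_t: float = math.inf
    init_t: float = math.inf
    term_t: float = math.inf
    reinit_t: float = math.inf
    preinit: bool = False
    inherited: bool = False

    def length_at(self, t: float) -> float:
        return self.L0 * math.exp((t - self.birth_t) / self.t0)


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def _reinit_length(rng, cfg: SimConfig, L0: float) -> float:
    """Per-cell re-initiation length threshold.

    Lognormal around the mean division length with an offset chosen so that
    re-initiation precedes division with probability ``p_preinit`` given the
    lognormal division-threshold noise.
    """
    from scipy.stats import norm as _norm
    spread = math.hypot(cfg.reinit_length_sd, cfg.division_length_noise_sd)
    mu = float(_norm.ppf(1.0 - cfg.p_preinit)) * spread
    return (cfg.division_length_factor * L0
            * math.exp(mu + rng.normal(0.0, cfg.reinit_length_sd)))


def _simulate_pair_chain(rng, cfg: SimConfig, frames, cell_id, pair_id, home,
                         p_resolved, rows):
    """Append emitter rows for one fork pair over a run of frames."""
    if len(frames) == 0:
        return
    b = 1.0 / max(cfg.resolved_dwell_frames, 1.0)     # resolved -> colocalized
    a = b * p_resolved / (1.0 - p_resolved) if p_resolved < 1 else 1.0
    e = rng.normal(0.0, cfg.confinement_sd)
    resolved = rng.random() < p_resolved
    sep = 0.0
    innov_sd = cfg.confinement_sd * math.sqrt(1 - cfg.confinement_rho ** 2)
    for i, f in enumerate(frames):
        if i > 0:
            e = cfg.confinement_rho * e + rng.normal(0.0, innov_sd)
            if resolved:
                resolved = rng.random() >= b
            else:
                if rng.random() < a:
                    resolved = True
                    sep = 0.0
        if resolved and sep == 0.0:
            sep = _truncated_normal(
                rng, cfg.resolved_sep_mean, cfg.resolved_sep_sd, 0.05, 0.32)
        if not resolved:
            sep = 0.0
        center = float(np.clip(home + e, 0.04, 0.96))
        if resolved:
            half = sep / 2
            xs = [np.clip(center - half, 0.02, 0.98),
                  np.clip(center + half, 0.02, 0.98)]
            for x in xs:
                rows.append((f, cell_id, pair_id, "resolved", float(x), 0.5, 0.5))
        else:
            rows.append((f, cell_id, pair_id, "colocalized", center, 0.5, 1.0))


def _active_frames(cfg, start_t, stop_t, first_frame, last_frame):
    """Frames f in [first, last] with start_t <= f*dt < stop_t."""
    dt = cfg.frame_interval_min
    lo = max(first_frame, int(math.ceil(start_t / dt)))
    hi = min(last_frame, int(math.ceil(stop_t / dt)) - 1)
    return range(lo, hi + 1) if hi >= lo else range(0)


def simulate_population(config: SimConfig, n_cells: int,
                        duration_min: float = 300.0) -> GroundTruth:
    """Simulate ``n_cells`` founder lineages for ``duration_min`` minutes.

    Deterministic given ``config.seed``.  In snapshot mode each founder is an
    independent cell observed in a single frame at a random cell-cycle phase
    (biased toward young cells, as in an exponentially growing population).
    """
    config.validate()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not config.snapshot and duration_min < config.frame_interval_min:
        raise ValueError("duration must cover at least one frame interval")
    if config.snapshot:
        return _simulate_snapshot(config, n_cells)

    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    n_frames = int(math.floor(duration_min / dt)) + 1
    last_frame = n_frames - 1

    cells: list[_Cell] = []
    next_id = 0

    def new_cell(parent_id, lane, order, birth_t, L0, inherited_init=None):
        nonlocal next_id
        t0 = _truncated_normal(rng, config.t0_mean_min, config.t0_sd_min,
                               60.0, 600.0)
        div_len = (config.division_length_factor * L0 *
                   math.exp(rng.normal(0.0, config.division_length_noise_sd)))
        c = _Cell(next_id, parent_id, lane, order, birth_t, L0, t0, div_len)
        next_id += 1
        c.birth_frame = max(0, int(math.ceil(birth_t / dt)))
        div_t = birth_t + t0 * math.log(div_len / L0)
        div_frame = int(math.ceil(div_t / dt))
        if div_frame <= last_frame:
            c.division_frame = div_frame
            c.div_t = div_frame * dt
        else:
            c.div_t = math.inf
        # replication round of this cell
        if inherited_init is not None:
            c.init_t = inherited_init
            c.inherited = True
        elif parent_id < 0 or config.reinit_enabled:
            delay = abs(rng.normal(config.d_period_mean_min,
                                   config.d_period_sd_min))
            c.init_t = birth_t + max(dt, delay)
        if math.isfinite(c.init_t):
            R = _truncated_normal(rng, config.replication_duration_mean_min,
                                  config.replication_duration_sd_min,
                                  30.0, 400.0)
            c.term_t = c.init_t + R
            if math.isfinite(c.div_t):
                # midcell foci always disassemble before division
                c.term_t = min(c.term_t, c.div_t - 2 * dt)
            if c.term_t <= c.init_t:
                c.term_t = c.init_t + dt
            # next-round initiation fires when the cell reaches a per-cell
            # re-initiation length (initiation-mass control).  The lognormal
            # offset is set so that P(L_init < L_division) = p_preinit; the
            # event lands before division exactly that often, and long cells
            # are the ones that have re-initiated.
            if config.reinit_enabled:
                L_init = _reinit_length(rng, config, L0)
                c.preinit = bool(L_init < c.div_len)
                if c.preinit:
                    t_Li = birth_t + c.t0 * math.log(L_init / L0)
                    c.reinit_t = max(t_Li, c.term_t + dt)
                    if math.isfinite(c.div_t):
                        c.reinit_t = min(c.reinit_t, c.div_t - dt)
        cells.append(c)
        return c

    # founders: one lineage per lane, each starting at birth
    queue = []
    for lane in range(n_cells):
        L0 = _truncated_normal(rng, config.birth_length_mean_um,
                               config.birth_length_sd_um, 1.0, 4.5)
        queue.append(new_cell(-1, lane, "0", 0.0, L0))
    # breadth-first division
    i = 0
    while i < len(queue):
        c = queue[i]
        i += 1
        if c.division_frame < 0:
            continue
        L_div = c.length_at(c.div_t)
        asym = rng.normal(0.0, config.division_asymmetry_sd)
        halves = (L_div * (0.5 + asym), L_div * (0.5 - asym))
        for side, Lb in enumerate(halves):
            inherited = c.reinit_t if c.preinit else None
            d = new_cell(c.cell_id, c.lane, c.order + ("L" if side == 0 else "R"),
                         c.div_t, Lb, inherited_init=inherited)
            d.parent_side = side  # type: ignore[attr-defined]
            queue.append(d)

    by_id = {c.cell_id: c for c in cells}
    rows: list[tuple] = []
    for c in cells:
        last_alive = (c.division_frame - 1 if c.division_frame >= 0
                      else last_frame)
        # quarter-cell factory pair inherited from the parent's re-initiation
        if c.inherited:
            parent = by_id[c.parent_id]
            side = getattr(c, "parent_side", 0)
            home_q = config.reinit_positions[side]
            qframes = _active_frames(config, parent.reinit_t, parent.div_t,
                                     parent.birth_frame, parent.division_frame - 1)
            _simulate_pair_chain(
                rng, config, list(qframes), parent.cell_id, c.cell_id, home_q,
                config.p_resolved * config.quarter_resolved_factor, rows)
        if math.isfinite(c.init_t):
            mframes = _active_frames(config, c.init_t, c.term_t,
                                     c.birth_frame, last_alive)
            _simulate_pair_chain(rng, config, list(mframes), c.cell_id,
                                 c.cell_id, 0.5, config.p_resolved, rows)
        # re-initiation happened but division lies beyond the simulated window:
        # the quarter-cell factories are still visible in this cell
        if c.preinit and c.division_frame < 0 and math.isfinite(c.reinit_t):
            p_q = config.p_resolved * config.quarter_resolved_factor
            for side, home_q in enumerate(config.reinit_positions):
                qframes = _active_frames(config, c.reinit_t,
                                         (last_frame + 1) * dt,
                                         c.birth_frame, last_frame)
                _simulate_pair_chain(rng, config, list(qframes), c.cell_id,
                                     -(c.cell_id * 2 + side + 1), home_q,
                                     p_q, rows)

    emitters = pd.DataFrame(
        rows, columns=["frame", "cell_id", "pair_id", "state", "x_rel",
                       "y_rel", "brightness"]
    ).sort_values(["frame", "cell_id", "pair_id"], kind="stable",
                  ignore_index=True)

    def frame_of(t):
        return int(math.ceil(t / dt)) if math.isfinite(t) else -1

    cells_df = pd.DataFrame([
        dict(
            cell_id=c.cell_id, parent_id=c.parent_id, lane=c.lane,
            order=c.order, birth_frame=c.birth_frame,
            division_frame=c.division_frame,
            birth_length_um=c.L0,
            division_length_um=(c.length_at(c.div_t)
                                if math.isfinite(c.div_t)
                                else c.length_at(min(duration_min, last_frame * dt))),
            t0_min=c.t0,
            init_frame=frame_of(c.init_t),
            term_frame=frame_of(c.term_t),
            reinit_frame=frame_of(c.reinit_t) if c.preinit else -1,
            preinit=bool(c.preinit),
            complete=c.division_frame >= 0,
        )
        for c in cells
    ])
    return GroundTruth(cells=cells_df, emitters=emitters, config=config,
                       n_frames=n_frames)


def _simulate_snapshot(config: SimConfig, n_cells: int) -> GroundTruth:
    """One frame per cell, each cell at a random phase of its cycle."""
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    rows: list[tuple] = []
    cell_rows = []
    for lane in range(n_cells):
        L0 = _truncated_normal(rng, config.birth_length_mean_um,
                               config.birth_length_sd_um, 1.0, 4.5)
        t0 = _truncated_normal(rng, config.t0_mean_min, config.t0_sd_min,
                               60.0, 600.0)
        div_len = (config.division_length_factor * L0 *
                   math.exp(rng.normal(0.0, config.division_length_noise_sd)))
        T = t0 * math.log(div_len / L0)
        tD = t0 * math.log(2.0)
        # exponential-population age distribution on [0, T)
        u = rng.random()
        tail = 1.0 - 2.0 ** (-T / tD)
        age = -tD * math.log2(1.0 - u * tail)
        inherited = rng.random() < config.p_preinit and config.reinit_enabled
        if inherited:
            init_t = -rng.uniform(5.0, 45.0)
        elif config.reinit_enabled:
            init_t = max(dt, abs(rng.normal(config.d_period_mean_min,
                                            config.d_period_sd_min)))
        else:
            init_t = 0.0
        R = _truncated_normal(rng, config.replication_duration_mean_min,
                              config.replication_duration_sd_min, 30.0, 400.0)
        term_t = min(init_t + R, T - 2 * dt)
        L_init = _reinit_length(rng, config, L0)
        preinit = config.reinit_enabled and L_init < div_len
        reinit_t = math.inf
        if preinit:
            reinit_t = max(t0 * math.log(L_init / L0), term_t + dt)

        def stationary_pair(cell_id, pair_id, home, p_res):
            e = rng.normal(0.0, config.confinement_sd)
            center = float(np.clip(home + e, 0.04, 0.96))
            if rng.random() < p_res:
                sep = _truncated_normal(rng, config.resolved_sep_mean,
                                        config.resolved_sep_sd, 0.05, 0.32)
                for x in (center - sep / 2, center + sep / 2):
                    rows.append((0, cell_id, pair_id, "resolved",
                                 float(np.clip(x, 0.02, 0.98)), 0.5, 0.5))
            else:
                rows.append((0, cell_id, pair_id, "colocalized", center, 0.5, 1.0))

        if init_t <= age < term_t:
            stationary_pair(lane, lane, 0.5, config.p_resolved)
        if reinit_t <= age:
            p_q = config.p_resolved * config.quarter_resolved_factor
            for side, home in enumerate(config.reinit_positions):
                stationary_pair(lane, -(lane * 2 + side + 1), home, p_q)
        # a snapshot stores the observed (current) length as the length
        # reference; the true birth length is unobservable in single frames
        L_now = L0 * math.exp(age / t0)
        cell_rows.append(dict(
            cell_id=lane, parent_id=-1, lane=lane, order="0", birth_frame=0,
            division_frame=-1, birth_length_um=L_now,
            division_length_um=L_now, t0_min=t0,
            init_frame=-1, term_frame=-1, reinit_frame=-1,
            preinit=bool(preinit), complete=False,
        ))
    emitters = pd.DataFrame(
        rows, columns=["frame", "cell_id", "pair_id", "state", "x_rel",
                       "y_rel", "brightness"])
    return GroundTruth(cells=pd.DataFrame(cell_rows), emitters=emitters,
                       config=config, n_frames=1)
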