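import numpy as np
import pandas as pd
import pytest

import replitrack as rt


class SmallRun:
    """A small E. coli-preset end-to-end run shared across test modules."""

    def __init__(self, n_cells=40, seed=11, duration=300.0,
                 preset_name="ecoli_dnaN"):
        self.config = rt.preset(preset_name)
        self.config.seed = seed
        self.truth = rt.simulate_population(self.config, n_cells, duration)
        self.fluor, self.masks, self.layout = rt.render_frames(
            self.truth, self.config)
        self.tracks = rt.build_tracks(self.masks, self.config.pixel_size_nm)
        self.fits = {c: rt.fit_growth(t, self.config.frame_interval_min)
                     for c, t in self.tracks.items()}
        self.selected = rt.select_cells(self.tracks, self.fits, "timelapse")
        self.foci = rt.detect_foci(self.fluor, self.masks, self.selected,
                                   rt.DetectionParams(),
                                   self.config.pixel_size_nm)
        self.pairs = rt.pair_separations(self.foci)
        self.mixture = rt.fit_mixture(self.pairs.rel_sep, seed=seed)
        self.classified = rt.classify_pairs(self.pairs, self.mixture)
        self.cell_frames = pd.DataFrame([
            dict(cell_id=c, frame=int(r.frame), length_um=r.length_um)
            for c, t in self.selected.items()
            for r in t.frames.itertuples()])
        self.counts = rt.count_factories(self.foci, self.classified,
                                         self.cell_frames)


@pytest.fixture(scope="session")
def small_run():
    return SmallRun()


@pytest.fixture(scope="session")
def noiseless_run():
    """A tiny noise-free render for localization round-trip checks."""
    cfg = rt.preset("ecoli_dnaN")
    cfg.seed = 5
    cfg.noise_model = "none"
    cfg.amplitude_cv = 0.0
    truth = rt.simulate_population(cfg, 10, 250.0)
    fluor, masks, layout = rt.render_frames(truth, cfg)
    return cfg, truth, fluor, masks, layout


def make_cell_image(shape=(26, 60), length_um=4.5, width_um=1.2,
                    pixel_size_nm=110.0, background=100.0,
                    emitters=(), psf_sigma_nm=160.0, noise_seed=None):
    """Hand-built single-cell image + mask for detection unit tests.

    ``emitters``: sequence of (x_px, y_px, amplitude).
    """
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    px_per_um = 1000.0 / pixel_size_nm
    L, W = length_um * px_per_um, width_um * px_per_um
    yy, xx = np.mgrid[0:h, 0:w]
    half = max(L / 2 - W / 2, 0)
    dx = np.clip(np.abs(xx - cx) - half, 0, None)
    mask = ((dx ** 2 + (yy - cy) ** 2) <= (W / 2) ** 2).astype(np.uint16)
    img = np.full(shape, background, dtype=float)
    sig = psf_sigma_nm / pixel_size_nm
    for ex, ey, amp in emitters:
        img += amp * np.exp(-((xx - ex) ** 2 + (yy - ey) ** 2) / (2 * sig ** 2))
    if noise_seed is not None:
        img = np.random.default_rng(noise_seed).poisson(img).astype(float)
    return img, mask
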