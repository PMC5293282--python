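import math

import numpy as np
import pandas as pd
import pytest

import replitrack as rt
from replitrack.detection import disk_offsets

from conftest import make_cell_image


class TestDiskGeometry:
    def test_radius_three_disk_has_29_pixels(self):
        assert rt.DetectionParams().disk_area == 29

    def test_offsets_within_radius(self):
        offs = disk_offsets(3)
        assert (offs[:, 0] ** 2 + offs[:, 1] ** 2 <= 9).all()


class TestDriftCorrect:
    def test_identical_frames_give_zero(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(200, size=(64, 64)).astype(float)
        assert rt.drift_correct(img, img) == (0, 0)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(200, size=(80, 80)).astype(float)
        shifted = np.roll(np.roll(img, 2, axis=0), 3, axis=1)
        dy, dx = rt.drift_correct(shifted, img)
        assert (dy, dx) == (2, 3)

    def test_injected_jitter_sequence_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(300, size=(72, 72)).astype(float)
        offsets = [(0, 0), (1, -2), (-3, 1), (2, 2)]
        prev = base
        for dy0, dx0 in offsets[1:]:
            cur = np.roll(np.roll(base, dy0, axis=0), dx0, axis=1)
            assert rt.drift_correct(cur, prev) == (dy0, dx0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            rt.drift_correct(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDetectCandidates:
    def test_flat_image_yields_no_candidates(self):
        img, mask = make_cell_image(emitters=())
        cands, _ = rt.detect_candidates(img, mask)
        assert cands == []

    def test_empty_mask_yields_no_candidates(self):
        img, mask = make_cell_image(emitters=((30.0, 13.0, 500.0),))
        cands, _ = rt.detect_candidates(img, np.zeros_like(mask))
        assert cands == []

    def test_two_emitters_600nm_apart_at_160nm_px_give_two_regions(self):
        px = 160.0
        half = 600.0 / px / 2
        img, mask = make_cell_image(
            shape=(20, 44), pixel_size_nm=px,
            emitters=((22 - half, 10.0, 1000.0), (22 + half, 10.0, 1000.0)))
        cands, _ = rt.detect_candidates(img, mask)
        assert len(cands) == 2

    def test_two_emitters_150nm_apart_merge_into_one_region(self):
        px = 160.0
        half = 150.0 / px / 2
        img, mask = make_cell_image(
            shape=(20, 44), pixel_size_nm=px,
            emitters=((22 - half, 10.0, 1000.0), (22 + half, 10.0, 1000.0)))
        cands, _ = rt.detect_candidates(img, mask)
        assert len(cands) == 1

    def test_candidates_exclude_out_of_mask_maxima(self):
        img, mask = make_cell_image(emitters=((30.0, 13.0, 800.0),))
        img[2, 2] += 5000.0  # bright spec outside any cell
        cands, _ = rt.detect_candidates(img, mask)
        assert all(mask[py, px] for py, px, _ in cands)


class TestFitFocus:
    def test_subpixel_position_recovered(self):
        img, mask = make_cell_image(emitters=((30.30, 12.60, 1500.0),))
        cands, _ = rt.detect_candidates(img, mask)
        focus = rt.fit_focus(img, cands[0])
        assert focus.x0 == pytest.approx(30.30, abs=0.05)
        assert focus.y0 == pytest.approx(12.60, abs=0.05)

    def test_symmetric_input_centers_on_pixel(self):
        img, mask = make_cell_image(emitters=((30.0, 13.0, 1500.0),))
        cands, _ = rt.detect_candidates(img, mask)
        focus = rt.fit_focus(img, cands[0])
        assert focus.x0 == pytest.approx(30.0, abs=1e-6)
        assert focus.y0 == pytest.approx(13.0, abs=1e-6)

    def test_width_matches_rendered_psf(self):
        img, mask = make_cell_image(emitters=((30.0, 13.0, 1500.0),))
        focus = rt.fit_focus(img, (13, 30, 1))
        expected_b = 160.0 / 110.0
        assert focus.b == pytest.approx(expected_b, rel=0.10)

    def test_candidate_at_border_dropped(self):
        img, mask = make_cell_image(emitters=((30.0, 13.0, 1500.0),))
        assert rt.fit_focus(img, (1, 1, 1)) is None


class TestScoreFocus:
    def _scored(self, img, mask, extra_params=None):
        params = extra_params or rt.DetectionParams()
        cands, blurred = rt.detect_candidates(img, mask, params)
        focus = rt.fit_focus(img, cands[0], params)
        dI = float(img[mask > 0].std())
        return rt.score_focus(blurred, focus, dI, params), blurred, dI

    def test_score_equals_brute_force_oracle(self):
        img, mask = make_cell_image(
            emitters=((30.2, 12.7, 1800.0),), noise_seed=3)
        focus, blurred, dI = self._scored(img, mask)
        # independent oracle: explicit python loops over the disk
        px, py = int(round(focus.x0)), int(round(focus.y0))
        vals = [blurred[py + dy, px + dx]
                for dy in range(-3, 4) for dx in range(-3, 4)
                if dx * dx + dy * dy <= 9]
        expected = ((sum(vals) - min(vals) * len(vals))
                    / (dI * math.sqrt(len(vals))))
        assert focus.score == pytest.approx(expected, rel=1e-9)

    def test_flat_disk_scores_zero_intensity(self):
        blurred = np.full((20, 20), 100.0)
        focus = rt.Focus(cell_id=1, frame=0, x0=10, y0=10, Ig=1, b=1, I0=100)
        scored = rt.score_focus(blurred, focus, 5.0)
        assert scored.Ia == 0.0
        assert scored.score == 0.0
        assert not scored.retained

    def test_flat_cell_deltaI_zero_rejected(self):
        blurred = np.full((20, 20), 100.0)
        blurred[10, 10] = 200.0
        focus = rt.Focus(cell_id=1, frame=0, x0=10, y0=10, Ig=1, b=1, I0=100)
        scored = rt.score_focus(blurred, focus, 0.0)
        assert scored.score == 0.0 and not scored.retained

    def test_retention_boundary_sits_exactly_at_threshold(self):
        # a synthetic disk with one raised pixel: Ia equals the raise, so the
        # score is fully controlled
        A = 29
        dI = 10.0
        for sigma, keep in ((3.9, False), (4.0, True), (4.1, True)):
            blurred = np.full((20, 20), 100.0)
            blurred[10, 10] += sigma * dI * math.sqrt(A)
            focus = rt.Focus(cell_id=1, frame=0, x0=10, y0=10,
                             Ig=1, b=1, I0=100)
            scored = rt.score_focus(blurred, focus, dI)
            assert scored.score == pytest.approx(sigma, rel=1e-12)
            assert scored.retained is keep

    def test_score_monotone_in_amplitude(self):
        # fixed noise field, amplitudes below score saturation
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 10, size=(26, 60))
        params = rt.DetectionParams()
        scores = []
        for amp in (30.0, 60.0, 120.0, 240.0):
            img, mask = make_cell_image(emitters=((30.0, 13.0, amp),))
            img = img + noise
            blurred = gaussian_filter(img, params.blur_sigma)
            focus = rt.Focus(cell_id=1, frame=0, x0=30.0, y0=13.0,
                             Ig=amp, b=1.45, I0=100.0)
            dI = float(img[mask > 0].std())
            scores.append(rt.score_focus(blurred, focus, dI, params).score)
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestDetectFoci:
    def test_pure_noise_false_positive_rate_below_two_percent(self):
        cfg = rt.preset("ecoli_dnaN")
        cfg.seed = 31
        truth = rt.simulate_population(cfg, 15, 250.0)
        truth.emitters = truth.emitters.iloc[0:0]  # no real foci at all
        fluor, masks, _ = rt.render_frames(truth, cfg)
        tracks = rt.build_tracks(masks, cfg.pixel_size_nm)
        foci = rt.detect_foci(fluor, masks, tracks, rt.DetectionParams(),
                              cfg.pixel_size_nm)
        n_cell_frames = sum(t.n_frames for t in tracks.values())
        assert n_cell_frames > 800
        assert len(foci) / n_cell_frames < 0.02

    def test_noiseless_emitters_matched_by_retained_foci(self, noiseless_run):
        cfg, truth, fluor, masks, layout = noiseless_run
        tracks = rt.build_tracks(masks, cfg.pixel_size_nm)
        foci = rt.detect_foci(fluor, masks, tracks, rt.DetectionParams(),
                              cfg.pixel_size_nm)
        lay = layout.set_index(["frame", "cell_id"])
        matched = total = 0
        for em in truth.emitters.itertuples():
            p = lay.loc[(em.frame, em.cell_id)]
            ex = p.x0_px + em.x_rel * p.length_px
            got = foci[(foci.frame == em.frame)
                       & (foci.cell_id == em.cell_id + 1)]
            if em.state == "resolved":
                # skip pairs below the diffraction limit of the renderer
                xr = truth.emitters[
                    (truth.emitters.frame == em.frame)
                    & (truth.emitters.pair_id == em.pair_id)].x_rel
                sep_px = (xr.max() - xr.min()) * p.length_px
                if sep_px < 4.5:
                    continue
            total += 1
            if len(got) and np.min(np.abs(got.x0 - ex)) <= 1.0:
                matched += 1
        assert total > 300
        assert matched / total > 0.97

    def test_localization_rms_below_half_pixel(self, small_run):
        lay = small_run.layout.set_index(["frame", "cell_id"])
        truth = small_run.truth
        coloc = truth.emitters[truth.emitters.state == "colocalized"]
        errs = []
        for em in coloc.itertuples():
            got = small_run.foci[
                (small_run.foci.frame == em.frame)
                & (small_run.foci.cell_id == em.cell_id + 1)]
            if len(got) != 1:
                continue
            p = lay.loc[(em.frame, em.cell_id)]
            ex = p.x0_px + em.x_rel * p.length_px
            errs.append(got.x0.iloc[0] - ex)
        assert len(errs) > 200
        assert np.sqrt(np.mean(np.square(errs))) < 0.5

    def test_four_plus_focus_cells_are_rare(self, small_run):
        per_cf = small_run.foci.groupby(["frame", "cell_id"]).size()
        n_cell_frames = sum(t.n_frames for t in small_run.selected.values())
        assert (per_cf >= 4).sum() / n_cell_frames < 0.01

    def test_detection_is_deterministic(self, small_run):
        again = rt.detect_foci(small_run.fluor, small_run.masks,
                               small_run.selected, rt.DetectionParams(),
                               small_run.config.pixel_size_nm)
        pd.testing.assert_frame_equal(again, small_run.foci)

    def test_retained_foci_meet_threshold(self, small_run):
        assert (small_run.foci.score >= 4.0).all()
        assert small_run.foci.retained.all()
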