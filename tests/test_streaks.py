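"""Streak-track recognition: conversion, thresholding, skeleton geometry."""

import math

import numpy as np
import pytest

from ciliametrics.calibration import ImageCalibration
from ciliametrics.streaks import (
    TrackFilterParams,
    annotate_overlay,
    binarize,
    extract_tracks,
    match_tracks_to_truth,
    skeleton_path_length_px,
    summarize_velocities,
    to_8bit,
)
from ciliametrics.synthetic import SwimFieldParams, simulate_swim_field


class TestTo8bit:
    @pytest.mark.parametrize("values,expected", [
        ([0, 65535], [0, 255]),            # endpoints of the linear map
        ([100, 200, 300], [0, 128, 255]),  # midpoint rounds half-to-even
    ])
    def test_linear_map(self, values, expected):
        img = np.array([values], dtype=np.uint32)
        assert to_8bit(img).tolist() == [expected]

    def test_constant_maps_to_zero(self):
        assert np.all(to_8bit(np.full((4, 4), 7, np.uint16)) == 0)

    def test_refuses_non_2d(self):
        with pytest.raises(ValueError, match="2-D"):
            to_8bit(np.zeros((2, 2, 2)))


class TestBinarize:
    def test_two_level_image_recovers_support(self):
        img = np.full((32, 32), 10, np.uint8)
        img[10:12, 4:28] = 200
        # smoothing off: thresholding alone must recover the exact support
        mask = binarize(img, TrackFilterParams(smooth_px=0.0, min_object_px=0))
        assert np.array_equal(mask, img == 200)

    def test_blank_image_empty_mask(self):
        assert not binarize(np.zeros((16, 16), np.uint8)).any()

    def test_noisy_simulated_field_overlaps_truth(self, streak_cal):
        """At SNR >= 10 the mask must overlap the noiseless streak support
        with Jaccard >= 0.7."""
        noisy = SwimFieldParams(n_cells=5, seed=3)
        clean = SwimFieldParams(n_cells=5, seed=3, shot_noise=False, read_noise_sd=0.0)
        img_n, _ = simulate_swim_field(noisy, streak_cal)
        img_c, _ = simulate_swim_field(clean, streak_cal)
        mask = binarize(to_8bit(img_n))
        truth_support = binarize(to_8bit(img_c))
        jac = (mask & truth_support).sum() / (mask | truth_support).sum()
        assert jac >= 0.7


class TestExtractTracks:
    def test_horizontal_streak(self, streak_cal):
        mask = np.zeros((20, 60), bool)
        mask[10, 5:55] = True  # 50 px long, 1 px wide
        (tr,) = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        assert tr.contour_length_um == pytest.approx(49.0)
        assert tr.end_to_end_um == pytest.approx(49.0)
        assert tr.velocity_actual_um_s == pytest.approx(49.0)
        assert tr.straightness == pytest.approx(1.0)

    def test_diagonal_streak(self, streak_cal):
        mask = np.zeros((40, 40), bool)
        idx = np.arange(5, 35)
        mask[idx, idx] = True  # 30 px at 45 degrees
        (tr,) = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        assert tr.contour_length_um == pytest.approx(29 * math.sqrt(2))

    def test_l_shape_matches_graph_oracle(self, streak_cal):
        """Contour of an L-shaped skeleton equals the brute-force weighted
        shortest path between its endpoints."""
        import networkx as nx

        mask = np.zeros((40, 40), bool)
        mask[5:35, 5] = True   # vertical arm, 30 px
        mask[34, 5:35] = True  # horizontal arm sharing the corner pixel
        (tr,) = extract_tracks(mask, streak_cal,
                               TrackFilterParams(min_contour_um=5, spur_prune_px=0))
        coords = [tuple(rc) for rc in np.argwhere(mask)]
        g = nx.Graph()
        for r, c in coords:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr or dc) and (r + dr, c + dc) in set(coords):
                        w = math.sqrt(2) if dr and dc else 1.0
                        g.add_edge((r, c), (r + dr, c + dc), weight=w)
        oracle = nx.shortest_path_length(g, (5, 5), (34, 34), weight="weight")
        assert tr.contour_length_um == pytest.approx(oracle, abs=1e-9)

    def test_branched_flagging(self, streak_cal):
        mask = np.zeros((41, 41), bool)
        mask[20, 2:39] = True
        mask[2:39, 20] = True  # a cross: 4 endpoints
        (tr,) = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        assert tr.branched and tr.flagged

    def test_border_flagging(self, streak_cal):
        mask = np.zeros((30, 30), bool)
        mask[0, 0:25] = True
        (tr,) = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        assert tr.touches_border

    def test_raster_order_numbering(self, streak_cal):
        mask = np.zeros((60, 60), bool)
        mask[40, 5:25] = True   # lower-left
        mask[10, 30:50] = True  # upper-right: first in raster order
        tracks = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        assert [t.track_id for t in tracks] == [1, 2]
        assert tracks[0].bbox[0] < tracks[1].bbox[0]

    def test_requires_exposure(self):
        cal = ImageCalibration(um_per_px=1.0)
        with pytest.raises(ValueError, match="exposure_s"):
            extract_tracks(np.zeros((5, 5), bool), cal)


class TestSkeletonOracle:
    def test_two_endpoint_skeletons_match_shortest_path(self, streak_cal, rng):
        """Property: on simulated single-cell streaks with exactly two
        endpoints the measured contour equals the weighted shortest path
        between the endpoints on the skeleton graph."""
        import networkx as nx
        from skimage.morphology import skeletonize

        checked = 0
        for seed in range(12):
            params = SwimFieldParams(
                n_cells=1, image_shape_px=(256, 256), speed_mean_um_s=120.0,
                speed_sd_um_s=30.0, seed=seed,
            )
            img, _ = simulate_swim_field(params, streak_cal)
            mask = binarize(to_8bit(img))
            if not mask.any():
                continue
            tracks = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
            for tr in tracks:
                if tr.branched or tr.skeleton_rc is None:
                    continue
                g = nx.Graph()
                pix = set(map(tuple, tr.skeleton_rc))
                for r, c in pix:
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if (dr or dc) and (r + dr, c + dc) in pix:
                                w = math.sqrt(2) if dr and dc else 1.0
                                g.add_edge((r, c), (r + dr, c + dc), weight=w)
                length, ep_a, ep_b, n_ep = skeleton_path_length_px(tr.skeleton_rc)
                if n_ep != 2:
                    continue
                oracle = nx.shortest_path_length(g, tuple(ep_a), tuple(ep_b),
                                                 weight="weight")
                assert length == pytest.approx(oracle, abs=1e-9)
                checked += 1
        assert checked >= 5

    def test_wobble_reduces_straightness(self, streak_cal):
        """Adding lateral wobble to the same seeded swimmer strictly lowers
        measured straightness relative to the straight-path control."""
        common = dict(n_cells=1, image_shape_px=(256, 256), speed_mean_um_s=100.0,
                      speed_sd_um_s=0.0, rot_diffusion_rad2_s=0.0,
                      substep_dt_s=0.001, seed=4)
        results = {}
        for amp in (0.0, 3.0):
            params = SwimFieldParams(wobble_amp_um=amp, wobble_freq_hz=20.0, **common)
            img, _ = simulate_swim_field(params, streak_cal)
            tracks = extract_tracks(binarize(to_8bit(img)), streak_cal,
                                    TrackFilterParams(min_contour_um=5))
            results[amp] = max(t.straightness for t in tracks)
        assert results[3.0] < results[0.0]

    def test_scale_invariance(self):
        """The same fields rendered at halved pixel size (with the
        pixel-denominated measurement parameters rescaled so the physical
        ones stay fixed) yield contour lengths with a median deviation
        within 3%. Per-field deviations carry heavy-tailed digitization
        noise from tip localization, so the median over fields is compared."""
        deviations = []
        for seed in (5, 11, 17, 23, 31):
            lengths = {}
            flagged = False
            for um_per_px in (1.0, 0.5):
                cal = ImageCalibration(um_per_px=um_per_px, exposure_s=1.0)
                shape = int(256 / um_per_px)
                params = SwimFieldParams(
                    n_cells=1, image_shape_px=(shape, shape),
                    speed_mean_um_s=100.0, speed_sd_um_s=0.0, seed=seed,
                )
                img, _ = simulate_swim_field(params, cal)
                fp = TrackFilterParams(min_contour_um=5,
                                       smooth_px=1.5 / um_per_px,
                                       spur_prune_px=int(5 / um_per_px))
                tracks = extract_tracks(binarize(to_8bit(img)), cal, fp)
                tr = max(tracks, key=lambda t: t.contour_length_um)
                flagged |= tr.flagged
                lengths[um_per_px] = tr.contour_length_um
            if not flagged:
                deviations.append(abs(lengths[0.5] / lengths[1.0] - 1))
        assert len(deviations) >= 3
        assert np.median(deviations) <= 0.03


class TestSummaries:
    def test_mean_and_sd(self, streak_cal):
        mask = np.zeros((60, 200), bool)
        mask[15, 10:101] = True   # 90 px -> 90 µm/s
        mask[40, 10:121] = True   # 110 px -> 110 µm/s
        tracks = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        s = summarize_velocities(tracks)
        assert s["n"] == 2
        assert s["mean_velocity_um_s"] == pytest.approx(100.0)
        assert s["sd_velocity_um_s"] == pytest.approx(np.std([90, 110], ddof=1))

    def test_all_flagged_gives_empty_summary(self, streak_cal):
        mask = np.zeros((30, 30), bool)
        mask[0, 0:20] = True  # touches border
        tracks = extract_tracks(mask, streak_cal, TrackFilterParams(min_contour_um=5))
        s = summarize_velocities(tracks, exclude_flagged=True)
        assert s["n"] == 0 and np.isnan(s["mean_velocity_um_s"])

    def test_velocity_recovery_on_matched_cells(self, streak_cal):
        """Median relative error of recovered vs true per-cell velocity stays
        below 5% on noiseless fields."""
        errs = []
        for seed in range(2):
            params = SwimFieldParams(seed=seed, shot_noise=False, read_noise_sd=0.0)
            img, truth = simulate_swim_field(params, streak_cal)
            tracks = extract_tracks(binarize(to_8bit(img)), streak_cal)
            m = match_tracks_to_truth(tracks, truth, streak_cal)
            errs.extend(abs(m["velocity_actual_um_s"] - m["true_speed_um_s"])
                        / m["true_speed_um_s"])
        assert len(errs) >= 20
        assert np.median(errs) <= 0.05

    def test_overlay_annotates_every_track(self, streak_cal):
        params = SwimFieldParams(n_cells=3, image_shape_px=(256, 256), seed=2)
        img, _ = simulate_swim_field(params, streak_cal)
        tracks = extract_tracks(binarize(to_8bit(img)), streak_cal)
        rgb = annotate_overlay(img, tracks)
        assert rgb.shape == (256, 256, 3)
        empty = annotate_overlay(img, [])
        assert np.array_equal(empty[..., 0], empty[..., 1])
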