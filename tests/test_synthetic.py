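"""Generator contracts: determinism, photon conservation, exact ground truth."""

import numpy as np
import pandas as pd
import pytest

from ciliametrics.calibration import ImageCalibration
from ciliametrics.synthetic import (
    BeatSimParams,
    CiliumSimParams,
    SwimFieldParams,
    beat_waveform,
    simulate_beat_video,
    simulate_cilium_profile,
    simulate_cilium_timelapse,
    simulate_swim_field,
)


class TestSwimField:
    def test_empty_field(self, streak_cal):
        params = SwimFieldParams(n_cells=0, read_noise_sd=0.0, seed=0)
        image, truth = simulate_swim_field(params, streak_cal)
        assert image.shape == params.image_shape_px
        assert np.all(image == 0)
        assert len(truth) == 0

    def test_uniform_linear_motion_ground_truth(self, streak_cal):
        """One cell at 100 µm/s without wander: contour = end-to-end = 100 µm."""
        params = SwimFieldParams(
            n_cells=1, speed_mean_um_s=100.0, speed_sd_um_s=0.0,
            rot_diffusion_rad2_s=0.0, wobble_amp_um=0.0, seed=5,
        )
        _, truth = simulate_swim_field(params, streak_cal)
        row = truth.iloc[0]
        assert row["contour_len_um"] == pytest.approx(100.0, rel=1e-12)
        assert row["end_to_end_um"] == pytest.approx(100.0, rel=1e-9)
        assert row["mean_speed_um_s"] == pytest.approx(100.0, rel=1e-12)

    def test_wobble_contour_exceeds_end_to_end(self, streak_cal):
        """With beat-locked wobble the arc length must exceed the chord, and
        the recorded contour must equal the numerically integrated arc
        length of the sub-stepped path."""
        params = SwimFieldParams(
            n_cells=1, speed_mean_um_s=100.0, speed_sd_um_s=0.0,
            rot_diffusion_rad2_s=0.0, wobble_amp_um=2.0, wobble_freq_hz=50.0,
            substep_dt_s=0.001, seed=7,
        )
        from ciliametrics.synthetic import _swim_paths

        px, py, _, _ = _swim_paths(params, streak_cal)
        oracle = np.hypot(np.diff(px), np.diff(py)).sum()
        _, truth = simulate_swim_field(params, streak_cal)
        row = truth.iloc[0]
        assert row["contour_len_um"] == pytest.approx(oracle, rel=1e-9)
        assert row["contour_len_um"] > row["end_to_end_um"]

    def test_photon_conservation_noiseless(self, streak_cal):
        """Sum of a noiseless streak equals photons/substep x substeps x
        in-field cells within the PSF truncation tolerance of 0.1%."""
        params = SwimFieldParams(
            n_cells=5, speed_mean_um_s=80.0, speed_sd_um_s=10.0,
            shot_noise=False, read_noise_sd=0.0, seed=21,
        )
        image, truth = simulate_swim_field(params, streak_cal)
        n_sub = int(round(streak_cal.exposure_s / params.substep_dt_s))
        # cells flagged in-field have their photons fully inside the frame
        n_in = int(truth["in_field"].sum())
        expected_min = params.photons_per_cell_per_substep * n_sub * n_in
        expected_max = params.photons_per_cell_per_substep * n_sub * len(truth)
        assert image.sum() >= expected_min * 0.999
        assert image.sum() <= expected_max * 1.001

    def test_determinism(self, streak_cal):
        params = SwimFieldParams(n_cells=3, seed=99)
        img1, t1 = simulate_swim_field(params, streak_cal)
        img2, t2 = simulate_swim_field(params, streak_cal)
        assert np.array_equal(img1, img2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_wobble_sampling_refusal(self, streak_cal):
        params = SwimFieldParams(wobble_amp_um=1.0, wobble_freq_hz=50.0,
                                 substep_dt_s=0.01)
        with pytest.raises(ValueError, match="wobble"):
            simulate_swim_field(params, streak_cal)

    def test_requires_exposure(self):
        cal = ImageCalibration(um_per_px=1.0)
        with pytest.raises(ValueError, match="exposure_s"):
            simulate_swim_field(SwimFieldParams(n_cells=1), cal)


class TestBeatVideo:
    def test_waveform_zero_mean_and_range(self):
        phase = np.linspace(0, 1, 20001)[:-1]
        for asym in (0.2, 0.25, 0.5, 0.8):
            w = beat_waveform(phase, asym)
            assert abs(w.mean()) < 1e-4
            assert w.min() == pytest.approx(-0.5, abs=1e-6)
            assert w.max() == pytest.approx(0.5, abs=1e-6)

    def test_efficiency_identity(self, video_cal):
        params = BeatSimParams(v_um_s=100.0, beat_freq_hz=50.0, seed=0)
        _, truth = simulate_beat_video(params, video_cal)
        assert truth["efficiency_um_per_beat"] == pytest.approx(2.0, rel=1e-12)
        assert truth["efficiency_um_per_beat"] * truth["beat_freq_hz"] == truth["v_um_s"]

    def test_zero_stroke_is_linear(self, video_cal):
        params = BeatSimParams(stroke_amp_um=0.0, noise_sd=0.0, seed=0)
        _, truth = simulate_beat_video(params, video_cal)
        x, t = truth["x_um"], truth["t_s"]
        fitted = np.polyfit(t, x, 1)
        assert fitted[0] == pytest.approx(params.v_um_s, rel=1e-9)
        assert np.max(np.abs(x - np.polyval(fitted, t))) < 1e-9

    def test_zero_velocity_returns_over_full_cycles(self, video_cal):
        params = BeatSimParams(v_um_s=0.0, beat_freq_hz=50.0, noise_sd=0.0,
                               duration_s=1.0, seed=0)
        _, truth = simulate_beat_video(params, video_cal)
        x = truth["x_um"]
        # after any integer number of cycles the centroid is back at start
        idx = np.arange(0, 1001, 20)[: len(x) // 20]  # every 50 Hz cycle at 1000 fps
        assert np.max(np.abs(x[idx] - x[0])) < 1e-9

    def test_undersampling_refusal(self, video_cal):
        with pytest.raises(ValueError, match="fps"):
            simulate_beat_video(BeatSimParams(beat_freq_hz=300.0), video_cal)


class TestCiliumProfile:
    def test_ground_truth_ratio_is_generator_arithmetic(self):
        params = CiliumSimParams(total_len_um=9.8, proximal_len_um=2.7,
                                 gap_len_um=1.0, distal_len_um=6.0)
        _, truth = simulate_cilium_profile(params)
        assert truth.ratio_distal_over_proximal == pytest.approx(6.0 / 2.7)
        assert truth.border_prox_end_um == 2.7
        assert truth.border_distal_start_um == 3.7

    def test_no_gap_is_single_region(self):
        params = CiliumSimParams(gap_len_um=0.0, distal_len_um=7.0)
        _, truth = simulate_cilium_profile(params)
        assert truth.no_gap_detected

    def test_zero_density_flags_no_signal(self):
        params = CiliumSimParams(density_proximal=0.0, density_distal=0.0)
        profile, truth = simulate_cilium_profile(params)
        assert truth.no_signal
        assert np.all(profile["intensity"] == 0)

    def test_region_overflow_refused(self):
        params = CiliumSimParams(total_len_um=5.0, proximal_len_um=2.7,
                                 gap_len_um=1.0, distal_len_um=6.0)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_cilium_profile(params)


class TestCiliumTimelapse:
    def test_zero_rate_no_events(self):
        params = CiliumSimParams(ift_rate_per_min=0.0, duration_s=30.0, seed=1)
        _, events = simulate_cilium_timelapse(params)
        assert events == []

    def test_event_count_matches_seeded_poisson_oracle(self):
        """The number of injected events equals an independent draw from the
        same documented seed discipline (first child stream, first draw)."""
        params = CiliumSimParams(ift_rate_per_min=6.0, duration_s=120.0, seed=31)
        _, events = simulate_cilium_timelapse(params)
        oracle_rng = np.random.default_rng(np.random.SeedSequence(31).spawn(3)[0])
        expected = int(oracle_rng.poisson(6.0 * 120.0 / 60.0))
        assert len(events) == expected

    def test_trace_kinematics(self):
        """An anterograde event at 2 µm/s on a 9.8 µm cilium is in transit
        for 4.9 s; the kymogram spot position advances accordingly."""
        params = CiliumSimParams(ift_rate_per_min=1.0, duration_s=60.0,
                                 noise_sd=0.0, seed=12)
        kym, events = simulate_cilium_timelapse(params)
        ev = next(e for e in events if e.t_start_s + params.total_len_um / e.speed_um_s
                  < params.duration_s)
        transit = params.total_len_um / ev.speed_um_s
        assert ev.span_um == pytest.approx(params.total_len_um)
        t_mid = ev.t_start_s + transit / 2
        row = kym[int(round(t_mid * params.fps))]
        static = np.median(kym, axis=0)
        x_peak = np.argmax(row - static) * params.um_per_px
        x_expected = (ev.speed_um_s * (t_mid - ev.t_start_s)
                      if ev.direction == "anterograde"
                      else params.total_len_um - ev.speed_um_s * (t_mid - ev.t_start_s))
        assert x_peak == pytest.approx(x_expected, abs=0.3)

    def test_determinism(self):
        params = CiliumSimParams(duration_s=20.0, noise_sd=0.05, seed=8)
        k1, e1 = simulate_cilium_timelapse(params)
        k2, e2 = simulate_cilium_timelapse(params)
        assert np.array_equal(k1, k2)
        assert [e.to_dict() for e in e1] == [e.to_dict() for e in e2]
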