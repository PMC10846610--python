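"""Predefined synthetic studies at the conditions of the original assays.

Each function simulates a complete recovery study — generate recordings at
the documented study conditions, run the measurement pipeline, compare with
ground truth — and returns a dict of summary quantities. They are the
backing for the acceptance checks and for `scripts/acceptance.py`.

Study conditions (chosen once, documented in docs/methods.md):

* Swimming: 1-s exposures of 1024x1024 px fields at 1 µm/px, 4 fields of
  25 cells per condition (100 cells), control speeds 120 ± 20 µm/s, the
  mastigoneme-deficient condition programmed 20% slower.
* Beating: 1-s clips at 1000 fps, 0.5 µm/px; control 120 µm/s at 60 Hz,
  mutant 96 µm/s at 64.8 Hz (-20% velocity, +8% frequency).
* Cilium regions: noiseless profiles at 0.1 µm/px spanning 4-23 µm cilia;
  region lengths follow the length-scaling rules distal = 0.8 L - 1.84 and
  proximal = 0.25 L + 0.25 (L < 10 µm) / 0.12 L + 1.55 (L >= 10 µm), with a
  1 µm gap.
* IFT: 5-min kymograms at 10 fps, read noise 0.1, Poisson event rates 0.81
  (full-length) and 0.35 (regenerating) events/min.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .calibration import ImageCalibration
from .ift import detect_events, event_frequency
from .kymo import analyze_beat_video
from .regions import RegionSegmentation, fit_length_trends, region_ratio, segment_regions
from .stats import compare_groups
from .streaks import (
    TrackFilterParams,
    binarize,
    extract_tracks,
    match_tracks_to_truth,
    skeleton_path_length_px,
    summarize_velocities,
    to_8bit,
)
from .synthetic import (
    BeatSimParams,
    CiliumSimParams,
    SwimFieldParams,
    simulate_beat_video,
    simulate_cilium_profile,
    simulate_cilium_timelapse,
    simulate_swim_field,
)

STREAK_CAL = ImageCalibration(um_per_px=1.0, exposure_s=1.0)
VIDEO_CAL = ImageCalibration(um_per_px=0.5, fps=1000.0)
TIRF_CAL = ImageCalibration(um_per_px=0.1, fps=10.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def nappi_ratio_worked_example() -> float:
    """Distal:proximal ratio from the printed mean region lengths of
    pyrophosphate-shortened cilia (distal 2.7 µm, proximal 1.5 µm)."""
    seg = RegionSegmentation(
        cilium_len_um=6.4, proximal_len_um=1.5, gap_len_um=1.0,
        distal_len_um=2.7, border_prox_end_um=1.5, border_distal_start_um=2.5,
    )
    return region_ratio(seg)


# ---------------------------------------------------------------------------
# swimming velocity
# ---------------------------------------------------------------------------

def streak_velocity_study(
    seed: int,
    n_fields: int = 4,
    control_speed: float = 120.0,
    mutant_factor: float = 0.8,
) -> dict:
    """Two-condition swimming study with per-cell matched recovery.

    Returns recovered vs true velocity statistics for the control and a
    programmed ``(1 - mutant_factor)*100`` percent slower mutant.
    """
    seeds = _child_seeds(seed, 2 * n_fields)
    results: dict[str, dict] = {}
    velocities: dict[str, list[float]] = {}
    for cond_i, (name, speed) in enumerate(
            [("control", control_speed), ("mutant", control_speed * mutant_factor)]):
        matched_meas, matched_true, summary_vals = [], [], []
        for k in range(n_fields):
            params = SwimFieldParams(
                speed_mean_um_s=speed, seed=seeds[cond_i * n_fields + k])
            image, truth = simulate_swim_field(params, STREAK_CAL)
            tracks = extract_tracks(binarize(to_8bit(image)), STREAK_CAL,
                                    TrackFilterParams())
            pairs = match_tracks_to_truth(tracks, truth, STREAK_CAL)
            matched_meas.extend(pairs["velocity_actual_um_s"])
            matched_true.extend(pairs["true_speed_um_s"])
            summary_vals.extend(
                t.velocity_actual_um_s for t in tracks if not t.flagged)
        mean_meas = float(np.mean(matched_meas))
        mean_true = float(np.mean(matched_true))
        results[name] = {
            "n_matched": len(matched_meas),
            "mean_recovered_um_s": mean_meas,
            "mean_true_um_s": mean_true,
            "recovery_err_pct": 100.0 * (mean_meas / mean_true - 1.0),
        }
        velocities[name] = summary_vals

    cmp_ = compare_groups(velocities["control"], velocities["mutant"],
                          "control", "mutant")
    results["percent_change"] = cmp_.percent_change
    results["p_value"] = cmp_.p_value
    results["programmed_change_pct"] = 100.0 * (mutant_factor - 1.0)
    return results


def skeleton_oracle_study(seed: int, n_streaks: int = 50) -> dict:
    """Contour length vs the weighted shortest-path oracle on random
    simulated single-cell streaks. Returns the worst absolute difference
    (pixel units) over all two-endpoint skeletons."""
    import networkx as nx

    seeds = _child_seeds(seed, n_streaks)
    max_diff, n_checked = 0.0, 0
    for s in seeds:
        params = SwimFieldParams(
            n_cells=1, image_shape_px=(256, 256), speed_mean_um_s=120.0,
            speed_sd_um_s=30.0, seed=s)
        image, _ = simulate_swim_field(params, STREAK_CAL)
        mask = binarize(to_8bit(image))
        if not mask.any():
            continue
        for tr in extract_tracks(mask, STREAK_CAL, TrackFilterParams(min_contour_um=5)):
            if tr.skeleton_rc is None or len(tr.skeleton_rc) < 2:
                continue
            length, ep_a, ep_b, n_ep = skeleton_path_length_px(tr.skeleton_rc)
            if n_ep != 2:
                continue
            g = nx.Graph()
            pix = set(map(tuple, tr.skeleton_rc))
            for r, c in pix:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr or dc) and (r + dr, c + dc) in pix:
                            w = math.sqrt(2) if dr and dc else 1.0
                            g.add_edge((r, c), (r + dr, c + dc), weight=w)
            oracle = nx.shortest_path_length(g, tuple(ep_a), tuple(ep_b),
                                             weight="weight")
            max_diff = max(max_diff, abs(length - oracle))
            n_checked += 1
    return {"n_checked": n_checked, "max_abs_diff_px": max_diff}


# ---------------------------------------------------------------------------
# beat metrics
# ---------------------------------------------------------------------------

def beat_grid_study(
    seed: int,
    velocities=(50.0, 90.0, 130.0, 150.0),
    frequencies=(40.0, 50.0, 60.0, 70.0),
) -> dict:
    """Recovery over the (v, f) grid: fraction of cases with velocity within
    5% and frequency within one spectral bin (1/duration)."""
    seeds = iter(_child_seeds(seed, len(velocities) * len(frequencies)))
    n_ok = n_total = 0
    worst_v_err = worst_f_err = 0.0
    for v in velocities:
        for f in frequencies:
            params = BeatSimParams(v_um_s=v, beat_freq_hz=f, seed=next(seeds))
            stack, _ = simulate_beat_video(params, VIDEO_CAL)
            m = analyze_beat_video(stack, VIDEO_CAL)
            # efficiency x frequency = velocity must hold to 1e-9 relative
            if not np.isnan(m.beat_freq_hz):
                ident = m.efficiency_um_per_beat * m.beat_freq_hz
                if abs(ident - m.velocity_um_s) > 1e-9 * max(1.0, abs(m.velocity_um_s)):
                    raise AssertionError("efficiency x frequency != velocity")
            v_err = abs(m.velocity_um_s - v) / v
            f_err = abs(m.beat_freq_hz - f)
            bin_hz = 1.0 / params.duration_s
            n_total += 1
            n_ok += int(v_err <= 0.05 and f_err <= bin_hz)
            worst_v_err = max(worst_v_err, v_err)
            worst_f_err = max(worst_f_err, f_err)
    return {
        "n_total": n_total,
        "fraction_ok": n_ok / n_total,
        "worst_velocity_err_frac": worst_v_err,
        "worst_frequency_err_hz": worst_f_err,
    }


def beat_two_condition_study(seed: int, n_cells: int = 10) -> dict:
    """Control vs mastigoneme-deficient beating: programmed -20% velocity
    and +8% beat frequency; returns the recovered percent changes."""
    conditions = {
        "control": BeatSimParams(v_um_s=120.0, beat_freq_hz=60.0),
        "mutant": BeatSimParams(v_um_s=96.0, beat_freq_hz=64.8),
    }
    seeds = iter(_child_seeds(seed, 2 * n_cells))
    metrics: dict[str, dict[str, list[float]]] = {}
    for name, base in conditions.items():
        vals = {"velocity": [], "frequency": [], "efficiency": []}
        for _ in range(n_cells):
            params = BeatSimParams(**{**base.__dict__, "seed": next(seeds)})
            stack, _ = simulate_beat_video(params, VIDEO_CAL)
            m = analyze_beat_video(stack, VIDEO_CAL)
            vals["velocity"].append(m.velocity_um_s)
            vals["frequency"].append(m.beat_freq_hz)
            vals["efficiency"].append(m.efficiency_um_per_beat)
        metrics[name] = vals
    out = {}
    for key in ("velocity", "frequency", "efficiency"):
        cmp_ = compare_groups(metrics["control"][key], metrics["mutant"][key])
        out[f"{key}_percent_change"] = cmp_.percent_change
        out[f"{key}_p_value"] = cmp_.p_value
    return out


# ---------------------------------------------------------------------------
# cilium regions and scaling trends
# ---------------------------------------------------------------------------

def scaling_rule(total_len_um: float) -> dict:
    """Region lengths for a cilium of the given length under the documented
    length-scaling rules (distal 0.8 µm/µm; proximal 0.25 below / 0.12 above
    the 10 µm breakpoint; 1 µm gap)."""
    L = total_len_um
    d = 0.8 * L - 1.84
    p = 0.25 * L + 0.25 if L < 10.0 else 0.12 * L + 1.55
    return dict(total_len_um=L, proximal_len_um=p, gap_len_um=1.0,
                distal_len_um=d)


def region_recovery_study(lengths=None) -> dict:
    """Noiseless segmentation recovery across the 4-23 µm regime. Returns
    the worst per-region absolute error in µm."""
    lengths = lengths if lengths is not None else np.arange(4.0, 23.0, 1.0)
    worst = {"proximal_len_um": 0.0, "gap_len_um": 0.0, "distal_len_um": 0.0}
    rows = []
    for L in lengths:
        params = CiliumSimParams(**scaling_rule(float(L)))
        profile, truth = simulate_cilium_profile(params)
        seg = segment_regions(profile)
        for name in worst:
            worst[name] = max(worst[name],
                              abs(getattr(seg, name) - getattr(truth, name)))
        rows.append({"cilium_len_um": float(L),
                     "proximal_len_um": seg.proximal_len_um,
                     "distal_len_um": seg.distal_len_um})
    return {"worst_err_um": worst, "max_err_um": max(worst.values()),
            "table": pd.DataFrame(rows)}


def trend_study(seed: int, n_cilia: int = 60) -> dict:
    """Length-scaling trend recovery from segmented noisy profiles.

    Cilium lengths are drawn uniformly over 4-23 µm; region lengths follow
    the scaling rules; profiles carry mild read noise. Returns the fitted
    slopes for both regions on both sides of the 10 µm breakpoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seeds = iter(_child_seeds(seed + 1, n_cilia))
    lengths = np.sort(rng.uniform(4.0, 22.9, n_cilia))
    rows = []
    for L in lengths:
        params = CiliumSimParams(**scaling_rule(float(L)), noise_sd=0.02,
                                 seed=next(seeds))
        profile, _ = simulate_cilium_profile(params)
        seg = segment_regions(profile)
        if seg.no_signal or seg.no_gap_detected:
            continue
        rows.append({"cilium_len_um": float(L),
                     "proximal_len_um": seg.proximal_len_um,
                     "distal_len_um": seg.distal_len_um})
    table = pd.DataFrame(rows)
    fits = {}
    for region in ("proximal", "distal"):
        fit = fit_length_trends(table, breakpoint_um=10.0,
                                y_col=f"{region}_len_um")
        fits[f"{region}_slope_below"] = fit.slope_below
        fits[f"{region}_slope_above"] = fit.slope_above
    # the distal region scales near-linearly over the whole range: one line
    overall = fit_length_trends(table, breakpoint_um=float("inf"),
                                y_col="distal_len_um")
    fits["distal_slope_overall"] = overall.slope_below
    fits["n_cilia"] = len(table)
    return fits


def control_region_study(seed: int, n_cilia: int = 50) -> dict:
    """Full-length control population (2.7 / 1 / 6 µm regions on 9.8 µm
    cilia) with noise: recovered mean lengths and distal:proximal ratio."""
    from .regions import summarize_regions

    seeds = iter(_child_seeds(seed, n_cilia))
    segs = []
    for _ in range(n_cilia):
        params = CiliumSimParams(noise_sd=0.05, seed=next(seeds))
        profile, _ = simulate_cilium_profile(params)
        segs.append(segment_regions(profile))
    return summarize_regions(segs)


# ---------------------------------------------------------------------------
# IFT rates
# ---------------------------------------------------------------------------

def ift_rate_study(seed: int, rate_per_min: float, n_recordings: int = 50) -> dict:
    """Poisson-injected IFT events at the given rate over seeded 5-min
    recordings; returns recovered vs realized frequencies plus detection
    recall and precision against the injected events."""
    seeds = _child_seeds(seed, n_recordings)
    rec, inj = [], []
    n_true = n_det = n_tp = 0
    for s in seeds:
        params = CiliumSimParams(ift_rate_per_min=rate_per_min, noise_sd=0.1,
                                 seed=s)
        kym, truth = simulate_cilium_timelapse(params)
        events = detect_events(kym, TIRF_CAL)
        rec.append(event_frequency(events, params.duration_s).combined_freq_events_min)
        inj.append(len(truth) / (params.duration_s / 60.0))
        used: set[int] = set()
        for ev in events:
            for i, g in enumerate(truth):
                if i in used:
                    continue
                if (ev.direction == g.direction
                        and abs(ev.t_start_s - g.t_start_s) < 4.0
                        and abs(ev.speed_um_s - g.speed_um_s) < 0.6):
                    used.add(i)
                    n_tp += 1
                    break
        n_true += len(truth)
        n_det += len(events)
    mean_rec, mean_inj = float(np.mean(rec)), float(np.mean(inj))
    return {
        "nominal_rate_per_min": rate_per_min,
        "mean_recovered_per_min": mean_rec,
        "mean_injected_per_min": mean_inj,
        "bias_vs_injected_pct":
            100.0 * (mean_rec / mean_inj - 1.0) if mean_inj > 0 else 0.0,
        "recall": n_tp / n_true if n_true else float("nan"),
        "precision": n_tp / n_det if n_det else float("nan"),
    }


# ---------------------------------------------------------------------------
# statistics calibration
# ---------------------------------------------------------------------------

def welch_null_study(seed: int, n_replicates: int = 1000, n: int = 10) -> dict:
    """Type-I error of the Welch comparison at alpha = 0.05 under the null."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        if compare_groups(a, b).p_value < 0.05:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates}
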