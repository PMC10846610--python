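"""Synthetic microscopy generator with exact ground truth.

Every measurement stage in this package is validated by parameter recovery:
the generator emulates the three kinds of recordings the measurements are
designed for and returns, alongside each image, the exact quantities the
measurement is supposed to recover.

* :func:`simulate_swim_field` — 1-s-exposure dark-field-like streak images of
  cells swimming at ~50–150 µm/s. Each cell is rendered as an isotropic
  Gaussian splat integrated along its sub-stepped path.
* :func:`simulate_beat_video` — 1000-fps bright-field-like clips of a single
  cell translating with beat-locked velocity modulation (fast power stroke,
  slow recovery stroke).
* :func:`simulate_cilium_profile` — TIRF-like fluorescence intensity along a
  cilium organized as a proximal plateau, a dim gap, and a distal plateau.
* :func:`simulate_cilium_timelapse` — 10-fps kymograms of a cilium containing
  a static distal region, diffusing proximal particles, and sparse diagonal
  IFT traces injected as a Poisson process.

Randomness discipline: each simulator derives child random streams from its
``seed`` via ``numpy.random.SeedSequence.spawn`` in a fixed, documented order,
so identical parameters and seed give bit-identical images and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .calibration import ImageCalibration
from .regions import RegionSegmentation
from .ift import IFTEvent

__all__ = [
    "SwimFieldParams",
    "BeatSimParams",
    "CiliumSimParams",
    "beat_waveform",
    "simulate_swim_field",
    "simulate_beat_video",
    "simulate_cilium_profile",
    "simulate_cilium_timelapse",
]


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class SwimFieldParams:
    """Conditions of a long-exposure swimming-field recording.

    Defaults emulate a healthy vegetative culture: mean speed 120 µm/s with
    20 µm/s cell-to-cell spread, mild directional wander, and photon counts
    giving a streak SNR of roughly 10. ``wobble_amp_um`` defaults to 0 because
    the beat-locked lateral oscillation of the cell body (~0.5 µm at ~50 Hz)
    is sub-pixel in a 1-s streak image; set it > 0 to emulate visibly wavy
    trajectories.
    """

    n_cells: int = 25
    image_shape_px: tuple[int, int] = (1024, 1024)
    speed_mean_um_s: float = 120.0
    speed_sd_um_s: float = 20.0
    rot_diffusion_rad2_s: float = 0.1
    wobble_amp_um: float = 0.0
    wobble_freq_hz: float = 50.0
    psf_sigma_um: float = 1.0
    photons_per_cell_per_substep: float = 80.0
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    substep_dt_s: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.speed_mean_um_s < 0 or self.speed_sd_um_s < 0:
            raise ValueError("speeds must be non-negative")
        if self.substep_dt_s <= 0:
            raise ValueError("substep_dt_s must be positive")
        if self.wobble_amp_um > 0 and self.wobble_freq_hz > 0:
            if self.substep_dt_s > 1.0 / (10.0 * self.wobble_freq_hz):
                raise ValueError(
                    f"substep_dt_s={self.substep_dt_s} is too coarse to sample a "
                    f"{self.wobble_freq_hz} Hz wobble; need <= "
                    f"{1.0 / (10.0 * self.wobble_freq_hz):.4g} s"
                )


@dataclass
class BeatSimParams:
    """Conditions of a high-speed clip of one translating, beating cell."""

    v_um_s: float = 100.0
    beat_freq_hz: float = 50.0
    stroke_amp_um: float = 1.0
    stroke_asymmetry: float = 0.25  # fraction of the cycle spent in the power stroke
    blob_sigma_um: float = 2.5
    duration_s: float = 1.0
    fps: float = 1000.0
    noise_sd: float = 5.0
    peak_intensity: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.stroke_asymmetry < 1.0):
            raise ValueError("stroke_asymmetry must lie strictly between 0 and 1")
        if self.fps < 4.0 * self.beat_freq_hz:
            raise ValueError(
                f"fps={self.fps} undersamples a {self.beat_freq_hz} Hz beat; "
                f"need fps >= {4.0 * self.beat_freq_hz}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class CiliumSimParams:
    """Geometry and imaging conditions of one cilium.

    Region defaults are the full-length control condition: a 2.7 µm proximal
    region and a 6 µm distal region separated by a 1 µm gap on a 9.8 µm
    cilium. The PSF sigma of 0.1 µm corresponds to high-NA TIRF optics.
    """

    total_len_um: float = 9.8
    proximal_len_um: float = 2.7
    gap_len_um: float = 1.0
    distal_len_um: float = 6.0
    density_proximal: float = 1.0
    density_distal: float = 1.0
    gap_leak_fraction: float = 0.05
    psf_sigma_um: float = 0.1
    um_per_px: float = 0.1
    noise_sd: float = 0.0
    margin_um: float = 1.0
    # time-lapse extras
    diffusion_coeff_um2_s: float = 0.05
    n_proximal_particles: int = 64
    proximal_particle_amplitude: float = 0.0625
    ift_rate_per_min: float = 0.8
    ift_antero_speed_um_s: float = 2.0
    ift_retro_speed_um_s: float = 3.0
    ift_amplitude: float = 1.5
    duration_s: float = 300.0
    fps: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        lengths = (self.proximal_len_um, self.gap_len_um, self.distal_len_um)
        if any(x < 0 for x in lengths):
            raise ValueError("region lengths must be non-negative")
        total_regions = sum(lengths)
        if total_regions > self.total_len_um + 1e-9:
            raise ValueError(
                f"proximal + gap + distal = {total_regions} µm exceeds the "
                f"cilium length {self.total_len_um} µm"
            )
        if self.um_per_px <= 0 or self.psf_sigma_um < 0:
            raise ValueError("um_per_px must be positive and psf_sigma_um non-negative")

    def validate_timelapse(self) -> None:
        self.validate()
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.ift_antero_speed_um_s <= 0 or self.ift_retro_speed_um_s <= 0:
            raise ValueError("IFT speeds must be positive")
        if self.ift_rate_per_min < 0:
            raise ValueError("ift_rate_per_min must be non-negative")


# ---------------------------------------------------------------------------
# streak fields
# ---------------------------------------------------------------------------

def _swim_paths(params: SwimFieldParams, cal: ImageCalibration):
    """Sub-stepped (x, y) positions in µm for every cell.

    Child streams, in order of consumption: 0 = initial positions/headings/
    speeds, 1 = rotational diffusion increments.
    """
    exposure = cal.require_exposure()
    n_sub = max(1, int(round(exposure / params.substep_dt_s)))
    dt = exposure / n_sub
    h_um = params.image_shape_px[0] * cal.um_per_px
    w_um = params.image_shape_px[1] * cal.um_per_px

    ss = np.random.SeedSequence(params.seed)
    init_rng, motion_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = params.n_cells
    x0 = init_rng.uniform(0, w_um, n)
    y0 = init_rng.uniform(0, h_um, n)
    theta0 = init_rng.uniform(0, 2 * np.pi, n)
    speeds = np.clip(
        init_rng.normal(params.speed_mean_um_s, params.speed_sd_um_s, n), 0, None
    )

    t = np.arange(n_sub + 1) * dt  # (n_sub+1,)
    dtheta = motion_rng.normal(
        0.0, math.sqrt(2.0 * params.rot_diffusion_rad2_s * dt), (n, n_sub)
    )
    theta = np.concatenate(
        [theta0[:, None], theta0[:, None] + np.cumsum(dtheta, axis=1)], axis=1
    )  # (n, n_sub+1)

    # base path: integrate speed along heading (heading held over each sub-step)
    step_x = speeds[:, None] * dt * np.cos(theta[:, :-1])
    step_y = speeds[:, None] * dt * np.sin(theta[:, :-1])
    bx = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(step_x, axis=1)], axis=1)
    by = np.concatenate([y0[:, None], y0[:, None] + np.cumsum(step_y, axis=1)], axis=1)

    # beat-locked lateral wobble, perpendicular to the instantaneous heading
    if params.wobble_amp_um > 0:
        osc = params.wobble_amp_um * np.sin(2 * np.pi * params.wobble_freq_hz * t)
        px = bx - osc[None, :] * np.sin(theta)
        py = by + osc[None, :] * np.cos(theta)
    else:
        px, py = bx, by
    return px, py, speeds, dt


def simulate_swim_field(
    params: SwimFieldParams, cal: ImageCalibration
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a long-exposure streak image and its per-cell ground truth.

    Returns
    -------
    image : float64 array, shape ``params.image_shape_px``
        Time-integrated photon image with optional Poisson shot noise and
        Gaussian read noise.
    truth : DataFrame
        One row per cell with ``contour_len_um`` (numerical arc length of the
        sub-stepped path), ``end_to_end_um``, ``mean_speed_um_s``
        (= contour / exposure) and ``in_field`` (whole path at least one PSF
        truncation radius inside the frame, so its photons are fully
        contained in the image).
    """
    params.validate()
    exposure = cal.require_exposure()
    shape = tuple(params.image_shape_px)

    if params.n_cells == 0:
        image = np.zeros(shape, float)
        if params.read_noise_sd > 0:
            ss = np.random.SeedSequence(params.seed)
            _, _, _, read_rng = [np.random.default_rng(s) for s in ss.spawn(4)]
            image = image + read_rng.normal(0, params.read_noise_sd, shape)
        truth = pd.DataFrame(
            columns=["cell_id", "contour_len_um", "end_to_end_um",
                     "mean_speed_um_s", "in_field",
                     "x_start_um", "y_start_um", "x_end_um", "y_end_um"]
        )
        return image, truth

    px, py, _, _ = _swim_paths(params, cal)
    steps = np.hypot(np.diff(px, axis=1), np.diff(py, axis=1))
    contour = steps.sum(axis=1)
    end_to_end = np.hypot(px[:, -1] - px[:, 0], py[:, -1] - py[:, 0])

    sigma_px = params.psf_sigma_um / cal.um_per_px
    margin_um = (math.ceil(6 * sigma_px) + 1) * cal.um_per_px
    h_um = shape[0] * cal.um_per_px
    w_um = shape[1] * cal.um_per_px
    in_field = (
        (px.min(axis=1) >= margin_um) & (px.max(axis=1) <= w_um - margin_um)
        & (py.min(axis=1) >= margin_um) & (py.max(axis=1) <= h_um - margin_um)
    )

    # deposit photons at sub-step start positions (bilinear), then blur once
    deposits = np.zeros(shape, float)
    cols = (px[:, :-1] / cal.um_per_px).ravel()
    rows = (py[:, :-1] / cal.um_per_px).ravel()
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    w_photon = params.photons_per_cell_per_substep
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                      (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.add.at(deposits, (rr[ok], cc[ok]), w_photon * w[ok])
    clean = gaussian_filter(deposits, sigma_px, mode="constant", truncate=6.0)

    ss = np.random.SeedSequence(params.seed)
    _, _, shot_rng, read_rng = [np.random.default_rng(s) for s in ss.spawn(4)]
    image = shot_rng.poisson(np.clip(clean, 0, None)).astype(float) if params.shot_noise else clean
    if params.read_noise_sd > 0:
        image = image + read_rng.normal(0, params.read_noise_sd, shape)

    truth = pd.DataFrame({
        "cell_id": np.arange(params.n_cells),
        "contour_len_um": contour,
        "end_to_end_um": end_to_end,
        "mean_speed_um_s": contour / exposure,
        "in_field": in_field,
        "x_start_um": px[:, 0],
        "y_start_um": py[:, 0],
        "x_end_um": px[:, -1],
        "y_end_um": py[:, -1],
    })
    return image, truth


# ---------------------------------------------------------------------------
# beating-cell videos
# ---------------------------------------------------------------------------

def beat_waveform(phase: np.ndarray, asymmetry: float) -> np.ndarray:
    """Zero-mean periodic displacement waveform of one beat cycle.

    ``phase`` is in cycles. The cell advances during the power stroke
    (fraction ``asymmetry`` of the cycle, half-cosine from -1/2 to +1/2) and
    drifts back during the slower recovery stroke (half-cosine back). Each
    half-cosine integrates to zero over its segment, so net displacement per
    cycle is exactly zero and the mean translation stays ``v``.
    """
    phi = np.mod(phase, 1.0)
    a = asymmetry
    power = phi < a
    out = np.empty_like(np.asarray(phi, dtype=float))
    out[power] = -0.5 * np.cos(np.pi * phi[power] / a)
    out[~power] = 0.5 * np.cos(np.pi * (phi[~power] - a) / (1.0 - a))
    return out


def simulate_beat_video(
    params: BeatSimParams, cal: ImageCalibration
) -> tuple[np.ndarray, dict]:
    """Render a high-speed clip of a cell whose centroid follows
    ``x(t) = v·t + stroke_amp·w(f·t)``.

    Returns the frame stack (frames, rows, cols) and a ground-truth dict with
    ``v_um_s``, ``beat_freq_hz``, ``efficiency_um_per_beat`` (= v/f exactly),
    and the per-frame times and centroid positions.
    """
    params.validate()
    um_per_px = cal.um_per_px
    fps = params.fps

    n_frames = int(round(params.duration_s * fps))
    t = np.arange(n_frames) / fps
    x_um = params.v_um_s * t + params.stroke_amp_um * beat_waveform(
        params.beat_freq_hz * t, params.stroke_asymmetry
    )

    sigma_px = params.blob_sigma_um / um_per_px
    pad_um = 4 * params.blob_sigma_um + params.stroke_amp_um
    x0_um = pad_um  # start offset so the blob never leaves the frame
    width_px = int(math.ceil((x_um.max() + 2 * pad_um) / um_per_px))
    height_px = int(math.ceil(2 * pad_um / um_per_px))
    yc_px = height_px / 2.0

    cols = np.arange(width_px)
    rows_g = np.exp(-0.5 * ((np.arange(height_px) - yc_px) / sigma_px) ** 2)
    stack = np.empty((n_frames, height_px, width_px), float)
    for i in range(n_frames):
        xc_px = (x0_um + x_um[i]) / um_per_px
        cols_g = np.exp(-0.5 * ((cols - xc_px) / sigma_px) ** 2)
        stack[i] = params.peak_intensity * rows_g[:, None] * cols_g[None, :]

    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        stack = stack + rng.normal(0, params.noise_sd, stack.shape)

    truth = {
        "v_um_s": params.v_um_s,
        "beat_freq_hz": params.beat_freq_hz,
        "efficiency_um_per_beat": params.v_um_s / params.beat_freq_hz,
        "t_s": t,
        "x_um": x_um + x0_um,
        "x0_um": x0_um,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# ciliary profiles and time-lapses
# ---------------------------------------------------------------------------

def _density_profile(params: CiliumSimParams, pos_um: np.ndarray) -> np.ndarray:
    """Base-to-tip fluorophore linear density sampled at ``pos_um``."""
    p, g, d = params.proximal_len_um, params.gap_len_um, params.distal_len_um
    dens = np.zeros_like(pos_um)
    dens[(pos_um >= 0) & (pos_um < p)] = params.density_proximal
    dens[(pos_um >= p) & (pos_um < p + g)] = (
        params.gap_leak_fraction * params.density_proximal
    )
    dens[(pos_um >= p + g) & (pos_um < p + g + d)] = params.density_distal
    return dens


def simulate_cilium_profile(
    params: CiliumSimParams,
) -> tuple[pd.DataFrame, RegionSegmentation]:
    """One TIRF-like intensity profile plus its exact segmentation.

    The profile is the plateau/gap/plateau linear density convolved with a
    1-D Gaussian PSF, sampled every ``um_per_px``, with optional additive
    Gaussian noise. Positions start at the ciliary base (0 µm) and extend
    ``margin_um`` past the cilium so the distal falling edge is sampled.
    """
    params.validate()
    n_px = int(math.ceil((params.total_len_um + params.margin_um) / params.um_per_px))
    pos = np.arange(n_px) * params.um_per_px
    dens = _density_profile(params, pos)
    sigma_px = params.psf_sigma_um / params.um_per_px
    intensity = gaussian_filter1d(dens, sigma_px, mode="nearest") if sigma_px > 0 else dens

    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        intensity = intensity + rng.normal(0, params.noise_sd, n_px)

    profile = pd.DataFrame({"position_um": pos, "intensity": intensity})

    p, g, d = params.proximal_len_um, params.gap_len_um, params.distal_len_um
    no_signal = params.density_proximal == 0 and params.density_distal == 0
    truth = RegionSegmentation(
        cilium_len_um=p + g + d,
        proximal_len_um=p if not no_signal else 0.0,
        gap_len_um=g if (g > 0 and not no_signal) else 0.0,
        distal_len_um=d if not no_signal else 0.0,
        border_prox_end_um=p,
        border_distal_start_um=p + g,
        no_gap_detected=(g == 0),
        no_signal=no_signal,
        weak_signal=False,
    )
    return profile, truth


def simulate_cilium_timelapse(
    params: CiliumSimParams,
) -> tuple[np.ndarray, list[IFTEvent]]:
    """Kymogram (rows = frames, cols = position) with known IFT events.

    Contents per frame: the static blurred distal plateau; ``n_proximal_particles``
    point particles diffusing within the proximal region (reflected Brownian
    steps of variance 2·D·dt); and IFT events injected as a Poisson process at
    ``ift_rate_per_min`` — anterograde events run base→tip at the anterograde
    speed, retrograde events tip→base. Gaussian read noise is added last.

    Child streams, in order: 0 = IFT events (count, times, directions),
    1 = particle diffusion, 2 = noise.
    """
    params.validate_timelapse()
    ss = np.random.SeedSequence(params.seed)
    event_rng, diff_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_frames = int(round(params.duration_s * params.fps))
    dt = 1.0 / params.fps
    n_px = int(math.ceil((params.total_len_um + params.margin_um) / params.um_per_px))
    pos = np.arange(n_px) * params.um_per_px
    sigma_px = max(params.psf_sigma_um / params.um_per_px, 1e-6)

    # static background: distal plateau + gap leak (the anchored PKD2 pool)
    static = gaussian_filter1d(_density_profile(params, pos), sigma_px, mode="nearest")

    # IFT events (consumed first from the event stream)
    L = params.total_len_um
    n_events = int(event_rng.poisson(params.ift_rate_per_min * params.duration_s / 60.0))
    t_starts = np.sort(event_rng.uniform(0.0, params.duration_s, n_events))
    antero = event_rng.random(n_events) < 0.5
    events: list[IFTEvent] = []
    for t0, is_antero in zip(t_starts, antero):
        speed = params.ift_antero_speed_um_s if is_antero else params.ift_retro_speed_um_s
        events.append(IFTEvent(
            direction="anterograde" if is_antero else "retrograde",
            t_start_s=float(t0),
            speed_um_s=float(speed),
            span_um=float(L),
            score=float("nan"),
        ))

    # diffusing proximal particles: free Brownian walk folded into [0, p_len]
    # (the mobile proximal pool is many individually faint molecules)
    p_len = max(params.proximal_len_um, params.um_per_px)
    npart = params.n_proximal_particles
    part_x0 = diff_rng.uniform(0, p_len, npart)
    step_sd = math.sqrt(2.0 * params.diffusion_coeff_um2_s * dt)
    diff_steps = diff_rng.normal(0.0, step_sd, (n_frames, npart))
    free = part_x0[None, :] + np.cumsum(diff_steps, axis=0)
    part_pos = p_len - np.abs(np.mod(free, 2 * p_len) - p_len)  # (frames, npart)

    kym = np.tile(static, (n_frames, 1))
    t_frames = np.arange(n_frames) * dt
    sigma_um = sigma_px * params.um_per_px
    part_amp = params.proximal_particle_amplitude * params.density_proximal
    if npart:
        chunk = max(1, int(4e6 // (npart * n_px)))
        for a in range(0, n_frames, chunk):
            b = min(a + chunk, n_frames)
            kym[a:b] += part_amp * np.exp(
                -0.5 * ((pos[None, None, :] - part_pos[a:b, :, None]) / sigma_um) ** 2
            ).sum(axis=1)
    # IFT traces: bright spots moving at constant speed
    for ev in events:
        transit = L / ev.speed_um_s
        i0 = max(0, int(math.ceil(ev.t_start_s / dt)))
        i1 = min(n_frames - 1, int(math.floor((ev.t_start_s + transit) / dt)))
        if i1 < i0:
            continue
        dt_ev = t_frames[i0:i1 + 1] - ev.t_start_s
        x = (ev.speed_um_s * dt_ev if ev.direction == "anterograde"
             else L - ev.speed_um_s * dt_ev)
        kym[i0:i1 + 1] += params.ift_amplitude * np.exp(
            -0.5 * ((pos[None, :] - x[:, None]) / sigma_um) ** 2)

    if params.noise_sd > 0:
        kym = kym + noise_rng.normal(0, params.noise_sd, kym.shape)
    return kym, events
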