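# Methods

`ciliametrics` quantifies four aspects of *Chlamydomonas* ciliary biology
from light microscopy: swimming velocity from long-exposure streak images,
ciliary beat frequency and beat efficiency from high-speed video, the
proximal/gap/distal organization of ciliary PKD2 fluorescence, and
intraflagellar transport (IFT) event frequency from TIRF time-lapses. Every
measurement is paired with a synthetic-data generator that produces the same
kind of recording with exact ground truth, so each stage is validated by
parameter recovery rather than by comparison with manual annotation.

## Streak velocimetry (`streaks`)

**Model.** During a 1-s exposure a swimming cell integrates into a bright
streak. The contour length of the streak divided by the exposure time is the
cell's actual velocity; the end-to-end distance gives the linear velocity.
Both are reported; the actual velocity is the default summary statistic.

**Procedure.** 8-bit conversion (linear min–max; half-values round to even)
→ mild Gaussian blur (`smooth_px`, default 1.5 px) → Otsu threshold (or a
fixed level) → removal of objects below `min_object_px` (10 px) →
8-connected components → topology-preserving thinning → spur pruning
(branches shorter than `spur_prune_px` = 5 px ending at a junction) →
weighted path length over the skeleton, orthogonal steps 1 px and diagonal
steps √2 px, scaled by the pixel size. The pre-threshold blur matters: shot
noise serrates the mask boundary, a serrated ribbon thins to a wiggly
centerline, and the wiggle inflates path lengths by several percent.

**Curation.** The original assay deleted false tracks by hand. Here every
exclusion is an explicit flag: `touches_border` (bounding box within
`border_margin_px` of the frame edge), `branched` (more than two skeleton
endpoints after pruning — crossing trajectories are flagged, never split),
and `below_min_length` / `above_max_length` (contour outside
[`min_contour_um`, `max_contour_um`], default 20–500 µm, which removes
debris and non-motile cells). Flagged tracks are kept in the table but
excluded from summaries by default. Track numbers follow the raster order of
bounding-box corners and carry no meaning.

**Known biases.** An 8-connected digitized line overestimates Euclidean
length by up to 8% depending on orientation (mean ≈ +5% over angles), while
thinning erodes roughly half the streak width at each tip (−2 to −3% for a
~100 µm streak). The two effects largely cancel; matched-pair recovery on
synthetic fields shows a residual +2 to +4% mean bias, within the 5%
tolerance the pipeline is validated to. Percent differences between
conditions are insensitive to this shared bias.

## Beat metrics (`kymo`)

**Model.** The cell body of a swimming cell advances with a beat-locked
modulation: `x(t) = v·t + A·w(f·t)` with `w` a zero-mean waveform with a
fast power stroke and slow recovery stroke. Beat efficiency — the distance
traveled per beat cycle — is `v / f` by definition, and the package asserts
`efficiency × frequency = velocity` (to 1e-9 relative) on every output.

**Procedure.** A kymogram is built by reslicing the stack along a line
(bilinear interpolation, perpendicular averaging over `width_px` = 5,
mirroring a wide reslice). Per row, the cell position is the
intensity-weighted centroid of pixels above `background + 0.25·(robust max −
background)` (background = kymogram median; robust max = 99.5th percentile),
with weights taken as the excess over the threshold so the quantized support
window does not bias the centroid. Velocity is the Theil–Sen slope of
position vs time — robust to the oscillation. Beat frequency is the highest
non-DC periodogram peak of the Theil–Sen-detrended trace, refined by
quadratic interpolation on log power; a peak below 10× the median power is
reported as undetermined (NaN), as is a numerically linear trace.

## PKD2 region segmentation (`regions`)

**Model.** The base-to-tip intensity profile of a PKD2-labelled cilium is a
proximal plateau, a dim gap (residual signal `gap_leak_fraction` of the
proximal level), and a distal plateau, convolved with the microscope PSF.

**Procedure.** The profile is smoothed (`smooth_um` = 0.2 µm), thresholded
at `frac_threshold` = 0.2 of the 98th-percentile robust maximum, and
decomposed into runs. The proximal region is the first run from the base;
the gap is the first sub-threshold run of at least `min_gap_um` = 0.4 µm;
the distal region runs from the gap's end to the last above-threshold pixel.
Each border is then refined to the half-level crossing between the
neighbouring plateau levels (plateau level = median of the run interior),
because the half-maximum crossing of a blurred step sits at the true edge
independent of blur width, whereas the raw fractional-threshold border is
displaced outward by ≈0.84·σ per edge — enough to violate the 0.2 µm
recovery bound once smoothing is included. The 0.2 µm smoothing default
(rather than a larger kernel) preserves detectability of ~0.8 µm gaps in
short regenerating cilia. With no qualifying gap the whole support is one
proximal region (`no_gap_detected`); with no signal, all lengths are zero
(`no_signal`). Lengths are half-open in pixel space; position 0 is the base.

**Ratio convention.** Both mean-of-ratios and ratio-of-means are computed;
mean-of-ratios is the default and the convention used is recorded in every
summary.

**Length-scaling trends.** Region length vs ciliary length is fitted as two
independent free-intercept OLS lines split at a breakpoint (default 10 µm,
separating regenerating/shortened from abnormally long cilia). The lines are
not constrained to meet; sides with fewer than 3 points are reported
unavailable. The synthetic scaling rules used in the recovery studies are
`distal = 0.8·L − 1.84` and `proximal = 0.25·L + 0.25` below /
`0.12·L + 1.55` above the breakpoint, with a 1 µm gap — consistent with a
9.8 µm control cilium carrying 2.7/1/6 µm regions.

## IFT event detection (`ift`)

**Model.** IFT particles cross the cilium at constant speed and appear as
straight diagonal kymogram traces (anterograde base→tip, retrograde
tip→base). Pausing and turnarounds are not modelled; an unbroken linear
segment counts as one event.

**Procedure.** Static and slowly varying background is removed by
per-column temporal median subtraction. Pixels above
`max(0.35 × 99.9th-percentile residual, 5 global MAD-sigmas, 6 per-column
MAD-sigmas)` vote in a Hough-style accumulator parametrized by signed speed
(geometric grid over ±0.5–5 µm/s, ~5% steps) and the time the line crosses
the kymogram midline. The per-column term raises the bar where the
background itself fluctuates (the diffusive proximal pool). The
best-supported line is refined by a weighted least-squares fit to the pixels
within a 0.4 µm corridor, the pixels are consumed, and voting repeats until
no candidate reaches `score_floor` = 15 pixels. A candidate becomes an
event only if its span is at least `min_span_um` = 2 µm, its refined speed
lies in the band, and its pixels cover at least half the frames *and* half
the columns of its extent — directed traces are present in every frame of
their transit and sweep every column of their span, whereas coincidental
alignments of diffusing particles are temporally dense but spatially
clumped. A deterministic accumulator (rather than a randomized probabilistic
Hough) makes mirroring the position axis swap anterograde and retrograde
counts exactly. Combined frequency is `(n_antero + n_retro) / minutes`.

**Limitations.** Events whose visible span is shorter than `min_span_um`
(e.g. starting just before the recording ends) are not scored, giving a
small (<2–3%) negative bias at 5-min recordings. IFT speeds are fixed
defaults (2 µm/s anterograde, 3 µm/s retrograde) typical of flagellar IFT;
the detector band is configurable.

## Group statistics (`stats`)

Two-group comparisons use Welch's unequal-variance two-tailed t-test
(Welch–Satterthwaite df), with a flag for the pooled-variance variant.
Zero-variance degenerate inputs are handled explicitly (equal means → t=0,
p=1; unequal → ±inf, p=0). Percent change is relative to the first group.
No multiple-testing correction is applied by default; Benjamini–Hochberg is
available and recorded when used. The unit of analysis for swimming
velocity is the track, not the cell.

## Synthetic data (`synthetic`)

What the generator emulates, and what it does not:

* **Streak fields** — cells as isotropic Gaussian splats (σ =
  `psf_sigma_um`) integrated along sub-stepped paths with rotational
  diffusion (0.1 rad²/s), optional beat-locked lateral wobble, Poisson shot
  noise and Gaussian read noise. Photons are deposited bilinearly and
  blurred once; with noise disabled, total intensity equals photons ×
  substeps × in-field cells to within 0.1% PSF truncation. Defaults: 25
  cells per 1024² px field at 1 µm/px, speeds 120 ± 20 µm/s (a healthy
  culture; mutants are programmed as fractional slowdowns), 80
  photons/substep giving streak SNR ≈ 10. `wobble_amp_um` defaults to 0:
  at 1-s exposure the ~0.5 µm body oscillation is sub-pixel, so a nonzero
  default would bake an unmeasurable arc-length into ground truth. Not
  emulated: cell shape, phototaxis, hydrodynamic interactions,
  photobleaching.
* **Beat clips** — a Gaussian blob translating with the piecewise-cosine
  waveform (duty cycle = `stroke_asymmetry` = 0.25, range ±stroke_amp/2,
  exactly zero mean per cycle so ground-truth efficiency is exactly v/f).
  1000 fps, 1 s, 0.5 µm/px; refusal below 4 samples per beat. Not emulated:
  the cilia themselves, cell rotation, focus drift.
* **Cilium profiles** — plateau/gap/plateau linear density convolved with a
  1-D Gaussian PSF (σ = 0.1 µm, high-NA TIRF) sampled at 0.1 µm/px.
  Control geometry 2.7/1/6 µm on a 9.8 µm cilium.
* **Time-lapses** — static distal signal; the mobile proximal pool as 64
  dim particles (amplitude 1/16 of the plateau) diffusing at 0.05 µm²/s
  with reflection; IFT events as a Poisson process (default 0.8/min)
  rendered as constant-speed bright traces (amplitude 1.5× plateau). The
  train/pool brightness contrast mirrors real kymograms, where trains are
  conspicuous against the dim diffusive background — with a pool rendered
  as few bright particles, PSF-scale coincidences would match train
  brightness and no detector (or human) could separate them. Not emulated:
  train pausing/turnaround, photobleaching, uneven illumination.

Randomness: every simulator spawns child streams from one seed in a fixed
documented order (`numpy.random.SeedSequence.spawn`), so identical
parameters and seed give bit-identical images and ground truth, and the
injected IFT event count is reproducible by an independent draw from the
same stream.

Passing recovery tests on these conditions shows the measurement pipeline is
correct and well-calibrated for data matching the generator's assumptions;
it does not certify performance on recordings with structured backgrounds,
drift, or optical artifacts the generator omits.

## Problem sizes in the standard studies

The predefined studies in `ciliametrics.studies` use: 4 fields × 25 cells
per swimming condition (100 cells); a 4 × 4 (velocity × frequency) beat
grid plus 10 clips per beat condition; 19 noiseless profile lengths spanning
4–23 µm plus 60 noisy profiles for trend fits and 50 for the control
population; 50-recording IFT studies for detection metrics and 200–300
recordings for frequency estimates (the 0.35 events/min condition yields
only ~1.75 events per 5-min recording, so frequency means need large n to
beat Poisson sampling noise); and 1000 replicates for the Welch null
calibration.
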