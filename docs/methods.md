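# Methods

This note documents the models, defaults and numerical choices behind
`kymoquant`, and what the synthetic-data validation does and does not
establish about real microscope data.

## Synthetic transport movies

`simulate_movie` emulates dual-colour line-scan imaging of vesicular
transport along a straight 1-D neurite.

**Geometry.** Defaults follow common acquisition settings for this kind of
experiment: 0.126 μm/px (a typical 100× EMCCD scale; the pixel size is
configurable because instruments differ), 3 fps simultaneous dual-colour
imaging (1.3 fps sequential mode is supported through the synchronization
offset), 3-minute movies, a ~60 μm field starting at the cell-body edge,
and a 5-pixel transverse line width.

**Channel assignment.** A vesicle is B-only with probability `p_b_only`
(default 0.25); otherwise it carries channel A and additionally carries
channel B with probability `p_colabel`. Under this model the fraction of
moving A vesicles co-transporting B converges to `p_colabel` exactly,
which makes the co-migration estimator directly checkable against a named
parameter. The presets `WT_SNB1_RAB3` (`p_colabel = 0.35`) and
`syd2_SNB1_RAB3` (`p_colabel = 0.15`) encode the wild-type and syd-2
mutant SNB-1/RAB-3 co-transport levels reported for this assay.

**Kinetics.** Each vesicle is anterograde, retrograde, bidirectional or
stationary (default mix 0.45/0.25/0.15/0.15 — anterograde-biased traffic
with a visible stationary pool). Moving vesicles switch between runs and
pauses with memoryless (exponential) waiting times: pause rate 0.2 /s and
mean pause 2 s by default, giving ~5 μm mean runs at the default speed
scale (Normal(1.0, 0.25) μm/s, floored at 0.15), i.e. ordinary saltatory
motor-driven motion rather than near-ballistic gliding. Bidirectional
vesicles additionally reverse at 0.05 /s. Positions are clamped to
[−0.5, L + 0.5] μm, so vesicles that reach a field boundary park there.

**Rendering and noise.** A vesicle of length ℓ is a box of physical
length ℓ convolved with a Gaussian PSF (σ = 0.2 μm), sampled at pixel
centres and spread over the transverse rows with the same Gaussian; for
ℓ ≳ 4σ the rendered FWHM equals ℓ, which the vesicle-length quantifier
relies on. Brightness defaults to 2000 photons/frame per vesicle over a
20 photon/px background — a comfortably detectable SNR chosen because the
source experiments report no brightness or noise figures; detector
robustness at lower SNR is therefore *not* established by these tests.
Poisson photon noise and Gaussian read noise (σ = 3) are applied per
channel, with per-channel generators split from the master seed at fixed
offsets so runs are bit-reproducible.

**Ground truth.** Every run emits a per-vesicle table (channels, class,
speed, length, net displacement, direction call by the net-displacement
rule) and a long-format per-frame position table; `truth.trace_table(ch)`
converts the latter into an ingestible annotation table, which is how the
acceptance checks decouple pipeline correctness from detector quality.

## Dendrite-extent cohorts

Reported per-genotype "% dendrite length with signal" values are cohort
sample statistics (mean ± SD over ~20 animals). `simulate_dendrite_cohort`
therefore builds a cohort whose truth extents are moment-matched
stratified normal quantiles — the sample mean and SD equal the preset
values exactly before clipping to [1, 99.5] % — rather than an iid draw,
whose 20-animal mean would wander by several points. The seed permutes
quantile assignment and drives pixel noise. Clipping biases the broadest
presets by up to ~2 points (downward at 69 ± 28, upward at 25 ± 25);
this, plus a sub-pixel edge-blur bias, is well inside the ±5-point
acceptance band and is visible in the recovered means. Profiles are
plateaus (signal 100, background 10, additive noise σ = 3, 1 px edge
blur) over a 40 μm dendrite plus a 5 μm signal-free distal tail used for
background estimation.

## Measurement conventions

- **Signal presence** (penetrance, extent): background mean + 3 SD, with
  at least 3 consecutive above-threshold samples, so a single hot pixel
  far from the soma cannot score as signal. Where no background region is
  designated, background statistics come from the dimmest intensity decile.
  Signal running through the most distal sampled point of a dendrite
  counts to the anatomical end (the sampling grid never lands exactly on
  the boundary).
- **Movement criterion**: |net displacement| ≥ 1 μm or ≥ 0.1 μm/s
  sustained for 3 frames (no quantitative criterion is standard; both
  constants are configurable). Direction ties are |net| < 2 px worth of
  μm; default policy excludes them, `tie_policy="last"` assigns the final
  direction of motion.
- **Pauses**: interval speed < 0.05 μm/s sustained ≥ 2 frames. Run
  lengths are per-segment |displacement| between pauses and reversals.
- **Trajectory intensity**: mean over non-pause anchors minus the mean at
  the same spatial positions shifted earlier by round(1 s / frame
  interval) rows (3 rows at 3 fps, 1 row at 1.3 fps).
- **Vesicle length**: FWHM (linear interpolation at half maximum) of the
  spatial profile at up to 5 rows near the ROI's mid-time, only for
  moving traces that share no ROI rows with another trace; ROIs are
  sampled uniformly with rejection of overlaps, seeded.
- **Co-migration matching**: one-to-one greedy matching by temporal
  overlap (ties by mean gap, then ids). A pair matches when it overlaps
  for ≥ 0.8 of the shorter trace's duration and the gap stays ≤ 0.5 μm at
  every compared time, or ≤ half the difference of the two vesicle
  extents when both are known (containment). Tolerances are defaults, not
  fitted: the human scoring they replace judged overlap by eye.

## Automated trace detection

`detect_traces` is a classical detector intended for well-separated
traffic; the pipeline's accuracy does not depend on it (annotated or
truth traces can always be ingested).

1. The per-column 20th-percentile intensity is subtracted first: it holds
   background plus structures present essentially always (true stationary
   clusters, reported as stationary traces), while sparing particles that
   merely dwell or oscillate in one zone — a temporal *median* proved too
   aggressive, carving holes wherever a slow particle lingered and
   distorting every trace passing through.
2. Rows are smoothed (σ = 1.5 px), peaks above a robust MAD-based
   threshold are linked row-to-row under a dual motion hypothesis — the
   particle keeps its fitted velocity or has just paused, the pause
   hypothesis carrying a 1.5 px penalty so it cannot steal a crossing
   particle's peak — with a tight gate for established tracks and a
   speed-limited gate for new ones; new tracks never spawn within 7 px of
   an active one.
3. Fragments are re-joined by gap closing (up to 25 rows) with
   forward/backward/zero-velocity extrapolation, junction trimming (the
   few anchors flanking a break are often corrupted by peak stealing),
   rejection of joins between fragments running in opposite directions,
   and velocity-consistency ranking; duplicate tracks that shadow one
   particle are fused when they agree within 3 px over ≥ 10 common rows.
4. Linked positions are smoothed with a centred 5-row moving average to
   suppress sub-pixel localization jitter before kinematic analysis.

Validation uses fields where ground-truth identity is well-posed
(particles spread along the neurite, within-direction speed ordering so
same-direction paths never cross, constant velocity as in plus-end comet
assays, ~50 opposite-direction crossings, default SNR); truth is
restricted to in-field frames. Mean precision and recall over three
seeded 20-particle movies exceed 0.9 at spatiotemporal IoU ≥ 0.5. Dense
saltatory traffic — convoys, co-moving pairs, particles parked at the
same boundary — is *not* identifiable at the trace level by any scorer,
human or automated, and is out of scope for the detector's guarantees.

## Statistics

Normality is gated per group (Shapiro–Wilk at the comparison's α); any
non-normal group routes the whole comparison to the nonparametric branch,
since a mixed parametric/nonparametric comparison is not meaningful.
Tests are two-sided: Student's t (equal variances) or one-way ANOVA with
Tukey's HSD on the parametric side, Mann–Whitney U or Kruskal–Wallis with
Dunn's post-hoc (tie-corrected rank z-tests, Holm-adjusted within the
post-hoc family) on the other. Under a true null the procedure rejects at
≈ α for both routes (checked over 500 seeded repetitions each). No
correction is applied across metrics.

## Limitations

- Straight neurites only; no curvature resampling, drift, bleaching,
  z-dimension, or cell-body entry/exit dynamics.
- The generator's brightness/noise defaults are chosen for comfortable
  detection; recovery results certify the measurement logic, not
  performance at adverse SNR.
- Sequential-mode synchronization stores a sub-frame time offset and
  honours it during trace interpolation; pixel data are never resampled.
- The detector guarantees above hold for resolvable traffic; crowded
  kymographs should be annotated manually and ingested.
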