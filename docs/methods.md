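# Methods

This note documents the models implemented in `larvascape`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Ratiometric activity measure

Soma activity is the fractional change of the background-subtracted
green/red ratio from its baseline:

    R(t)   = (green(t) − bg_g(t)) / (red(t) − bg_r(t))
    R₀     = mean of the lowest 10% of R over the track
    ΔR/R₀  = (R − R₀) / R₀

Any intensity factor m(t) > 0 common to both channels cancels exactly in R,
which is what makes the green/red pair robust to motion-induced intensity
changes. Design points:

* **Background** defaults to the per-channel, per-timepoint mean of voxels
  at or below the 5th percentile (a dark-floor estimate robust to cell
  motion); a user-supplied static box is the alternative. Under untruncated
  Gaussian noise the sub-percentile mean is biased low by ≈ 2.06 σ; in
  practice camera data (and this package's renders) are clipped at zero, so
  the dark floor concentrates at the true offset and the estimator is
  accurate there. The bias is worth knowing about for offset-shifted data.
* **Baseline count** is ⌈0.10·N⌉ of the *defined* ratio samples, never
  fewer than one.
* **Undefined ratios** (red at or below background) are excluded, not
  clamped — clamping would bias R₀ downward. Traces need at least 10
  defined samples.
* **ROI** is the axis-aligned box of half-width cell radius + 1 µm margin
  around the tracked position (a box that encompasses the whole cell body);
  boxes clipped by the volume boundary are averaged over the intersection
  and flagged.

## Tracking

The red (static) channel is the fiducial. Each seeded soma is followed
frame to frame by iterated intensity-weighted centroiding inside a sphere of
radius 15 µm (covers inter-frame motion at 10 volumes/s for observed crawl
speeds) around the previous position:

1. the search window is denoised with a Gaussian matched filter (σ = 2 µm,
   about the soma scale) — linear and symmetric, so the centroid of a
   symmetric soma profile is unchanged while read-noise jitter roughly
   halves;
2. voxels above half the window maximum are centroided (weights = intensity
   above threshold), the window re-centred, and the step repeated until the
   estimate moves < 0.1 voxel (max 20 iterations).

The pipeline is invariant to multiplying the movie by a positive scalar, and
deterministic. Candidates of different tracks converging within one cell
radius (3 µm) are re-assigned by minimal total displacement (optimal
one-to-one assignment within the conflicting cluster, ties broken by cell_id
order) and flagged `low` for supervision. Windows with no signal above
background mark the track lost; lost tracks are truncated, never
extrapolated. Manual corrections overwrite a position (flag `corrected`) and
re-run tracking forward from that frame; a correction outside the valid
range must be adjacent to it.

## Contraction events and time normalization

Segment contraction is proxied by the 3-D inter-cell distance d(t) between a
neuron and its homolog in the adjacent segment. Choices:

* **Resting length** = 90th percentile of d over the trace; a high quantile
  is robust to the dwell time spent contracted.
* **Smoothing** 0.3 s moving average before minima detection — suppresses
  frame noise at 10 volumes/s without distorting events in the 0.7–2.5 s
  range (set it to 0 for analytically constructed traces).
* **Detection**: local minima with excursion ≥ 15% of the resting length.
* **FWHM** is measured on the excursion (resting − d) with sub-sample
  linear interpolation; on Gaussian dips it recovers 2.355 σ to within one
  volume period. Events whose half-max crossings leave the recording are
  excluded (`edge`).
* **Exclusions**: events where d does not re-attain 95% of the resting
  length before the next event are dropped (`no-return`); at most the first
  two qualifying events per neuron enter averages (`max-two-per-neuron`) —
  "first two" is chronological.
* **Normalization**: the event time axis becomes (t − t_max)/FWHM on a
  fixed grid [−3, +3] A.U., step 0.05 (wide enough to contain both phase
  windows with headroom); ΔR/R₀ is optionally divided by its within-window
  maximum. Contraction phase = [−1, +1] A.U. (mean of ΔR/R₀ replaced by the
  window max), resting phase = [−1.5, −1] A.U. (window mean).
* **Half-max timing** is the first *rising* crossing of 50% of the window
  maximum (activation timing), sub-sample interpolated. Lags between cell
  types are tested with a one-tailed paired t test (exact t tail,
  df = n − 1); zero-variance differences are refused rather than reported
  as p = 0 or 1.

All event statistics are invariant to uniform time translation.

## Two-bar exploration model

The anterior larva is abstracted as two rigid bars of length 2p (default
p = 25 µm): the posterior bar fixed with midpoint at the origin, the
anterior bar at midpoint separation S(t), rotated rigidly by θ(t) about the
posterior midpoint. With corners D1L/D1R (anterior) and D2L/D2R
(posterior), the exact left/right inter-cell distances follow from the
rotated corner coordinates and satisfy

    r_exact² = (S ± p·sin θ)² + p²(1 − cos θ)²,

so the linear model r = S ± p·sin θ is accurate to second order. The
coordinate construction is taken as the authoritative exact model; a
closed-form rendering of the exact distance in the literature of this model
can acquire a spuriously duplicated leading linear term in print, which is
dimensionally inconsistent — expanding the corner geometry shows the square
root alone is the distance.

Worst-case relative deviation of the linear model, per side, normalized by
the exact distance: ≈ 0.143% over p = 25 µm, S ∈ [3p, 5p], |θ| ≤ 30°
(attained at S = 3p, θ = ±30°). The often-quoted "< 0.12%" figure for this
geometry is reproduced either by normalizing the deviation by the separation
S (≈ 0.120%), by measuring it on the difference/sum metrics (≈ 0.103%), or
by restricting to |θ| ≲ 28.6°; `scripts/acceptance.py` reports the
per-side, exact-normalized number over the full grid.

Sign convention: positive θ turns toward the larva's left, shortening r_L
and lengthening r_R (so the stored turning metric r_L − r_R = −2p·sin θ; a
`positive_theta="right"` flip is available). Decomposition of real tracks
projects the four 3-D tracks onto their joint least-squares plane (the model
is planar), estimates p̂ as half the mean D2L–D2R distance, and recovers
θ = arcsin((r_L − r_R)/(−2p̂)) with out-of-range values clamped and
flagged, and S as the retraction metric / 2. Lagged correlations between
movement metrics and calcium search one-sided non-negative delays of
calcium only (deformation causes the transient), on a grid of one volume
period.

## Synthetic generator

The generator is the package's test bed and defines its study conditions:

* **Crawl**: segment lengths L_i(t) = L₀(1 − A·g_i(t)) with a Gaussian
  wave envelope per segment (A = 0.35, σ = 0.4 s → contraction FWHM
  ≈ 0.94 s, inside the 0.7–2.5 s range typical of larval crawling), onsets
  advancing posterior→anterior at 1 segment/s, repeating every 6 s, tail
  anchored. Default 4 segments of 80 µm, half-width p = 25 µm. Cells sit at
  segment boundaries (types staggered 8 µm along the body axis), homologous
  left/right pairs at x = ±p, so homolog distance equals segment length
  exactly.
* **Explore**: θ(t) a seeded two-component low-frequency sinusoid (max
  25°), S(t) = 100 + 12·sin(2π·0.3t + φ) µm, feeding the two-bar pose.
* **Calcium**: dc/dt = gain·u − c/τ with τ = 0.4 s (fast indicator decay)
  and drive u = rectified fractional length change of the cell's segment —
  contraction-rectified for class I/dmd1/vbd analogs, stretch-rectified for
  the dbd analog. The rectified-linear transfer is the simplest choice
  consistent with deformation-coupled activity; it is a stand-in, not an
  inference about the biology. gain = 8 gives peak ΔR/R₀ ≈ 1.1 for a 35%
  contraction and ≥ 5× separation from a calcium-insensitive (GFP) control
  at the default noise. Optional per-type onset delays emulate sequential
  activation. Integration uses the exact exponential step for
  piecewise-constant drive, so closed-form solutions are reproduced exactly
  at sample times.
* **Rendering**: somata as isotropic 3-D Gaussians (σ = 3 µm) on a 2 µm
  isotropic grid; red amplitude static (100), green = 100·(1 + c); both
  channels share m(t) = 1 + 0.1·sin(2π·0.5t) (motion-induced intensity
  modulation); additive Gaussian read noise (sd 10 → peak SNR 10) then
  clipping at 0. Rendering is float64 so that exact-cancellation properties
  of the ratio can be asserted to < 1e−9. One root seed; deterministic
  per-component substreams; identical config + seed is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optics (PSF anisotropy, depth-dependent blur,
scattering), dendrite morphology (somata only), Poisson photon statistics
(noise is additive Gaussian), bleaching, non-rigid body deformation beyond
the prescribed kinematics, occlusions, and neighboring non-target
fluorescence. Tracking and extraction accuracies measured here are
best-case for the stated SNR.

## Problem sizes and runtime

The validation suite uses one 6 s crawl movie (60 volumes, ~19×185×50
voxels, 8 cells) per noise condition, one 10 s exploration movie, and 100
trace-level replicates (9 segments, 8 pairs, three cell types) for the
sequential-activation power check — sizes chosen so the whole suite runs in
well under a minute per movie while leaving the statistical checks
adequately powered. Sequential-activation power is evaluated at the trace
level (generator kinematics + calcium + ΔR/R₀ noise, sd 0.05); the rendered
path (render → track → extract → events) is exercised end-to-end by the
tracking, invariance, and exploration checks and by the event-closure test.

## Known limitations

* The deskew applies only the oblique-angle x-shear (linear interpolation,
  zero fill); no deconvolution, destriping or resampling onto isotropic
  voxels.
* Background estimation and the dark-floor bias discussed above.
* The tracker needs a visible, roughly symmetric soma on the red channel;
  it does not detect cells, handle long occlusions, or model soma shape
  change.
* The two-bar decomposition assumes planar, rigid-bar geometry; strong
  out-of-plane motion degrades θ and S estimates in ways the planar
  projection cannot repair.
* p-values from the paired lag test are exact under normality of the paired
  differences; with n = 5–8 pairs, heavy-tailed timing noise will make them
  approximate.
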