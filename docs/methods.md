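# Methods

This note documents the models, parameters and numerical choices behind
`endotrack`, and what the synthetic validation does and does not show
about real data.

## Motion model (synthetic_data)

Particles alternate between *rests* and *runs* as an alternating renewal
process with exponential durations (means `mean_rest_duration`,
`mean_run_duration`).  The stationary run-time fraction is
µ_run / (µ_run + µ_rest), and the time-averaged fraction over an
observation window T is asymptotically normal with variance
2 µ_rest² µ_run² / (µ_rest + µ_run)³ / T for exponential durations — this
closed form is the oracle for the renewal-convergence tests.

Each run keeps a single direction, drawn radially toward the cell centre
with probability `inward_fraction` (otherwise away), with Gaussian angular
jitter (default 15°) to mimic an imperfectly radial microtubule array.
Within a run, motion is a chain of constant-speed straight segments: the
speed is redrawn per segment, the segment distance is exponential with mean
1.4 µm truncated below at 0.1 µm, and only the speed changes at segment
boundaries.  An optional `max_run_distance` cap truncates runs, which is
how motor-inhibited conditions are emulated.  Observed positions are the
noiseless construction plus i.i.d. Gaussian localization noise per
coordinate (default 20 nm).

Parameter defaults and their reasoning:

- **Segment speeds: uniform on [0.5, 8] µm/s.**  The phenomenon of interest
  is clear directed translocation with peak speeds up to ~8 µm/s.  A
  speed law with heavy mass below ~0.5 µm/s puts most *run time* into
  sub-pixel-scale crawling, which the contour-smoothing step of the
  analysis suppresses *by design* (see below); such conditions are not
  recoverable by this method and are not what its thresholds were built
  for.  The uniform law keeps a broad speed range while all runs produce
  resolvable displacement.
- **Run-fraction presets (`params_for_run_fraction`)** hold the mean run
  duration at 5 s (a persistent multi-micrometre translocation, an order
  of magnitude above the smoothing scale) and derive the rest duration
  from the requested fraction, so the classifier's fixed per-run edge cost
  is the same across conditions.
- **`control_params`**: rests ~2.5 s, runs ~1.5 s, full speed range —
  a motile population that produces passages out to 9 µm and beyond.
- **`inhibited_params`**: rests ~20 s, runs ~0.4 s, speeds ≤ 4 µm/s,
  runs capped at 3 µm — a strongly inhibited population.  Because single
  runs cannot exceed 3 µm and runs are rare and non-collinear, Euclidean
  passages of ≥ 7 µm are structurally (not just statistically) absent.
- **Movie rendering** draws each particle as an isotropic Gaussian of
  width `psf_sigma` (px) and applies Poisson noise with the photon gain
  chosen so the peak signal-to-noise ratio equals `peak_snr`.  The
  background is constant or a linear ramp, which is the canonical failure
  mode for naive threshold detection.

Not emulated: photophysics (blinking, bleaching), 3-D motion, motion blur
within a frame, heterogeneous spot sizes, and interactions between
particles.  Passing tests therefore demonstrate correctness of the
analysis pipeline under the stated motion model, not robustness to every
imaging artefact of real movies.

## Tracking

Detection high-pass filters each frame (subtraction of a wide Gaussian
blur, σ = 10 px) so constant or linearly ramped background produces no
candidates; local maxima above a robust threshold (median + 5 MAD-σ of
the filtered interior) are accepted, none closer than `min_separation`.
A margin of one background-σ at the image border is excluded, where the
filter residual is unreliable.

Subpixel refinement fits a second-order polynomial to the local patch by
weighted least squares with a Gaussian weight (σ = expected spot radius)
centred on the candidate, and takes the fitted extremum; a fit whose
extremum escapes the window flags the detection as rejected rather than
raising.  Shape metrics come from intensity-weighted central moments of
the background-subtracted patch: radius = √(µ₂₀+µ₀₂), eccentricity from
the covariance eigenvalues, and a dimensionless third-moment magnitude as
skewness.  Default acceptance bounds were calibrated on rendered
single-spot and fused-doublet fixtures.

Linking is greedy one-to-one nearest-neighbour between consecutive
frames (candidate pairs taken in order of increasing distance, capped at
`max_displacement`); no gap closing — broken tracks are repaired later by
stitching.  At SNR ≥ 10 the localization RMS error is below 0.15 px on
rendered fixtures.

## Stitching, contours and x(T)

Fragments are merged when one begins 1–14 frames after, and within 5 px
of, another's end; competing joins resolve by smallest frame gap then
smallest spatial gap, joins chain transitively, and gap frames are filled
by linear interpolation and flagged.  The operation is idempotent.

The smoothed contour replaces each track point by the mean of all track
points within L<sub>pix</sub> = 0.340 µm (one pass), then coarsens by
walking the smoothed track and emitting group means each time the
cumulative path separation exceeds L<sub>pix</sub>; terminal edges are
extended linearly by L<sub>pix</sub> beyond the raw extremes.  This
smoothing deliberately suppresses motion below the L<sub>pix</sub> scale
(short oscillations are imaging noise at these settings), which also
means the first and last ~L<sub>pix</sub> of travel of every genuine run
is compressed toward the adjacent rest position — the dominant, and
quantified, bias of run/rest recovery (a few percent of run time for
multi-second runs).

Projection assigns each smoothed point the arc length of its nearest
point on the coarse polyline, with three safeguards for self-approaching
contours, where bare nearest-point projection is ill-posed: (i) after the
first frame, candidates are restricted to an arc window of (raw
inter-frame displacement + 2 L<sub>pix</sub>) around the previous arc
position, making x contraction-safe; (ii) distances tied within 20 nm
resolve toward the previous arc, then toward the lower arc (so an
out-and-back passage over one path retraces rather than wrapping); and
(iii) if the windowed foot is more than L<sub>pix</sub>/2 farther than
the global nearest point, lock is declared lost and the projection
re-acquires globally — the only situation in which x may jump.

## Run/rest segmentation

A frame is a rest if it lies in any window of **more than** 14 frames
whose x-range is below 85 nm (maximal windows found by a two-pointer
sweep with monotonic deques, O(n)).  Remaining sections are runs iff
their |x| displacement is ≥ 85 nm at a mean rate ≥ 0.17 µm/s; failing
sections merge into the neighbouring rest (the convention for sections
the thresholds cannot classify).  Boundary semantics: exactly 14 frame
intervals is not a rest; exactly 85 nm counts as a run displacement.
Population summaries average per-movie run-time fractions with their
standard error across movies; the never-running percentage is per
particle.

Direction is classified against the outward radial direction (cell
centre → track start): outward iff the net-displacement vector makes an
angle strictly below 90° with it, 90° exactly classifying inward.  This
is equivalent to measuring against the start→centre vector with the
complementary rule, and is unit-tested on the axis-aligned cases.

## First-passage probability

For each starting time point T of each track, the first-passage time at
length L is the smallest positive lag at which the Euclidean displacement
of the raw (stitched, unsmoothed) positions reaches L; a tolerance of
1 nm guards the exact-boundary case against float rounding.  Every T
counts toward the normalization whether or not it yields a passage, so
per-L total probability is passages / time points ≤ 1.  Overlapping
passages are intentional.  The optimized implementation scans the
pairwise displacement matrix in chunks and is tested for exact equality
against a literal O(n²) double loop.  Speed bins default to 60
logarithmic bins over [0.05, 20] µm/s.  Note that measured passage
speeds u = L/t *underestimate* the instantaneous speed by up to one
frame of rounding (v(t−Δt)/t < u ≤ v for constant speed v), and that
passages spanning rests dilute u further — mean passage speed is a
population statistic, not a motor speed.

The static error is the same computation on fixed-cell (noise-only)
tracks, reported per L and optionally as a percentage of a reference
condition's passage rate; it is appreciable only at the smallest L and
falls off steeply with L.

## Parsing

x(T) of long (> 2 µm net displacement) tracks is decomposed into
constant-speed segments by exact dynamic programming over segment
boundaries: per-segment cost is the OLS line-fit SSE (O(1) via cumulative
sums of 1, t, t², x, xt, x²), plus a per-segment penalty
β σ̂² log n with β = 10 and σ̂ estimated robustly from second differences
(MAD-based; the second difference of line-plus-noise has sd σ√6).  A
strictly positive penalty floor makes the noiseless case identifiable
(fewest segments win ties exactly).  Pieces may be as short as 3 samples
so brief recoil artefacts can be isolated, but fitted pieces spanning
fewer than 3 frame intervals are discounted from output, and segments
overlapping interpolated (stitched) frames can be excluded.  β was
calibrated once on simulated curves with known change points; at 20 nm
noise and clearly distinct adjacent slopes, segment counts are recovered
essentially always, with sub-percent median speed error and ≤ 1 frame
median change-point error.

Survival curves report the cumulative frequency of segment speeds,
excluding segments at or below 0.9 µm/s (the clear-displacement
criterion); fast-run selection uses a strict > 5 µm/s.  Percentage
tables over labelled counts round to one decimal and make no attempt to
reconcile externally supplied counts.

## Problem sizes

Validation suites use populations of 40–100 tracks of 1,000–4,000 frames
(36–143 s at 28 frames/s) — enough that the sampling error of run-time
fractions (≈1–1.5 percentage points s.e.) is well below the 5-point
recovery tolerance, and that rare-event assertions (zero long passages in
the inhibited condition) carry structural rather than statistical margin.
Parsing recovery uses 200 curves of 2–5 segments each.

## Known limitations

- Run/rest recovery is biased low by the contour smoothing's per-run edge
  cost; conditions dominated by runs much shorter than ~1 µm, or by
  speeds ≪ 0.5 µm/s, are outside the method's resolving power.
- Linking is greedy and gap-free; dense fields with crossing particles
  will swap identities where spacing approaches `max_displacement`.
- The projection's global re-acquisition can produce isolated arc jumps
  on heavily self-crossing tracks (~0.1% of frames in simulation).
- The change-point parser assumes piecewise-linear x(T) with independent
  Gaussian noise; strongly correlated noise (e.g. slow focus drift) would
  require a recalibrated penalty.
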