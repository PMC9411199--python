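# Methods

This note documents the models, parameters and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying protocol
left the choice open.

## Motion correction

Coronal two-photon recordings of the cervical connective move with the
animal: large translations plus smaller, smooth non-affine deformations.
Because GCaMP fluorescence is activity-dependent, all motion estimation
uses the co-expressed anatomical marker (red channel); the identical
transform is applied to the green channel.

**Center-of-mass (COM) pre-alignment.** Each frame's intensity center of
mass is matched to the reference frame (frame 0) by an integer-pixel
shift. The COM is computed on median-subtracted intensity (clipped at
zero): the uniform background otherwise dominates the mass and the COM
barely responds to anatomy motion. The public COM operation fills
exposed edges with zeros; inside the two-channel pipeline the offset is
instead used to *seed* the optic-flow field, so the data are never
resampled twice and no zero-filled band enters the flow estimate.

**Variational optic flow.** The dense field w = (u, v), mapping
reference coordinates to frame coordinates (backward warping), minimizes

    E(w) = sum_p (Ix u + Iy v + It)^2 + lambda * (|grad u|^2 + |grad v|^2)

with `lambda_smooth = 800`. Both images are Gaussian-smoothed
(sigma = 1 px) and jointly rescaled to a fixed 0–255 range before
differentiation, so the weight has the same meaning across acquisitions.
The energy is minimized coarse-to-fine over a 3-level Gaussian pyramid
(downscale 2), with 3 warp/re-linearization steps per level. Each
linearization is quadratic; on levels up to `exact_solve_max_px = 8000`
pixels its Euler–Lagrange system is solved exactly by a sparse direct
factorization, while larger levels run up to 100 Jacobi-style
Horn–Schunck iterations (tolerance 1e-4 px mean change). The exact
coarse solves matter because iterative diffusion propagates flow into
untextured background regions only slowly; a field that is wrong over
the background would still *correct* well but would not recover the true
deformation there. On synthetic movies with ≤ 5 px rigid plus ≤ 2 px
non-rigid motion and noise up to ~5 % of signal amplitude, the mean
endpoint error of the recovered fields is ≈ 0.3 px (< 0.5 px).

Warping is bilinear (`scipy.ndimage.map_coordinates`, order 1), with
out-of-bounds samples taking the nearest edge value.

**Longitudinal projections** are registered by windowed subpixel
cross-correlation (mean subtraction + Hann window before the FFT; the
window suppresses circular-boundary artifacts that otherwise bias the
correlation peak by several tenths of a pixel on smooth images).

## Photometry

**Illumination correction.** The temporal-mean image is median filtered
((71, 91) kernel at full acquisition scale, reflect boundaries) and
Gaussian filtered (sigma = 3 px) to remove single-neuron features, then
averaged over y. A least-squares line is fit to the most central 200
columns of this x profile and every column is divided by the line
(normalized to 1 at the image center). A fit whose line crosses zero
inside the frame is refused. The correction aids visualization only:
because a pixel's signal and its baseline are multiplied by the same
factor, dF/F is exactly invariant when the same line divides both. (It
is *not* invariant to recomputing the baseline through the spatial
smoothing chain, which does not commute with a per-column gain; the
pipeline divides first and computes dF/F afterwards, so the distinction
is immaterial in practice.) At the reduced synthetic frame sizes the
kernel and central width scale down ((31, 31) and 64 columns in the
desk-scale study pipeline).

**Baseline and dF/F.** F0 is the per-pixel minimum across all trials of
the smoothed signal: spatial Gaussian sigma = 10 px, then a centered
10-sample temporal boxcar (~0.6 s at 16 Hz) with truncated, renormalized
edges. The centered window is a choice — a causal window would bias F0
late — and is applied identically everywhere. F0 is floored at
epsilon = 1e-6 x (global max intensity) so the ratio (F - F0)/F0 is
always defined; dF/F is then bounded below by -1.

**Temporal denoising.** Each interior frame is predicted per pixel by a
local linear regression over the 30 frames before and 30 after it
(~2 s each side at 16 Hz), excluding the frame itself. With a symmetric
window the regression's prediction at the center equals the neighborhood
mean (the slope term cancels), so the operation is implemented as an
exclusive 60-frame average: it passes slow calcium transients nearly
unchanged and divides white-noise variance by ~60. Border frames are
returned unmodified and flagged. This interpolate-from-neighbors
contract replaces network-based denoising at desk scale; it does not
model shot-noise statistics or spatial noise correlations.

## Treadmill processing

Sensor readings (two sensors x two axes, 400 Hz) are smoothed with an
80-sample (~200 ms) centered moving average, then inverted through a
fixed linear geometry: sensors at azimuth +-45 deg view the ball's
equator, each reporting a horizontal flow cos(45)f -/+ sin(45)s and a
vertical flow equal to the turning rate. The 4 x 3 matrix has full
column rank; the pseudo-inverse averages the two redundant turning
channels. The synthetic generator uses the same forward model, so
inversion is validated by round trip. The exact physical sensor layout
of a given rig differs; on real data the matrix should be replaced by
the rig's calibration, behind the same interface.

Stationarity: sample s is stationary iff all three |rates| < 0.01 rot/s
(0.31 mm/s surface speed on a 10 mm ball: 0.01 x pi x 10 = 0.314) *and*
at least 75 % of samples within +-0.5 s are below threshold; edge
windows use available samples only. The context rule removes brief
pauses between walking bouts. Synchronization to the two-photon clock
averages all samples falling in each frame interval [i/f, (i+1)/f);
boolean traces use majority vote; an empty interval yields NaN with a
warning.

## Wave analysis

Per fly: the connective-mean trace of every trial is divided by the 99th
percentile (linear-interpolation definition) of the concatenated
pre-feeding trials. The per-period "maximum" activity is the 99th
percentile of the normalized trace — an upper percentile bound rather
than the single largest sample, which would be noise-dominated. By
construction the pre-feeding statistic is exactly 1 for every fly.

Group comparisons use Mann–Whitney U tests (one-sided for the caffeine
contrasts, following the directional hypothesis that caffeine increases
activity). Two methods are exposed: `exact` enumerates the permutation
null (preferred at n <= 8 per group) and `normal_cc` uses the
tie-corrected, continuity-corrected normal approximation. At n = 3 vs 3
under complete separation the approximation gives p = 0.040 while the
exact null gives p = 0.05 — the approximation, not the exact test, is
what can fall below the 0.05 threshold at these group sizes, and it is
the default for the caffeine contrasts for that reason.

Wave timing: T_peak is the (earliest, on ties) maximum of the
connective-mean trace. Pixel peak times are the argmax, within
T_peak +- 10 s, of the stack smoothed with a temporal Gaussian
(sigma = 10 samples, ~0.62 s) and spatial Gaussian (sigma = 1 px),
reported relative to T_peak; a window extending past the recording is
clipped with a warning. ROI display traces are Gaussian-smoothed
(sigma = 3 samples) and min–max normalized.

## Arena locomotion

Signed translational velocity is the magnitude of the Savitzky–Golay
first derivative (order 2) of the centroid, negated when the
displacement opposes the heading. The filter window is 9 frames
(112 ms at 80 fps): the derivative is exact on quadratic motion, and the
shorter window keeps the corner-rounding bias at the velocity minimum
inside the 5 % metric-recovery budget on noise-free tracks; longer
windows (e.g. 15) trade accuracy at the response onset for more noise
suppression and remain available as a parameter.

Per stimulation epoch: response slope = (min velocity - onset velocity) /
time-to-minimum (0 with a warning if the minimum is at onset); backward
distance = left Riemann sum of velocity over epoch frames with v < 0
(frame value x 1/80 s); maximum negative velocity = the epoch minimum.
Epochs with strictly more than 0.3 s of cumulative wall contact, or any
dorsally-flipped frame, are excluded. The default protocol is 30 s
spontaneous + three 3 s stimulations with 10 s inter-stimulus intervals
(onsets 30, 43, 56 s; 59 s total).

## Degradation quantification

Daily projections are registered (translation only) to day 1; ROI masks
drawn on day 1 are held fixed; per-day, per-ROI mean fluorescence is
normalized by the day-1 mean of the same (fly, ROI) — so day 1 is
exactly 1 and the measure is invariant to overall gain. Groups are
compared per day with a two-sided exact Mann–Whitney test (group sizes
are 5 here; the exact null is used whenever both groups are <= 8). Decay
rates are re-estimated by a log-linear fit of the normalized values from
day 2 onward.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (spec, seed); noise is additive
Gaussian clipped at zero.

**Connective movies.** Axon cross-sections are 2-D anisotropic Gaussians
truncated to ellipses, placed in four bands mimicking the connective's
regions (giant fibers at the dorsal midline, dorsomedial, dorsolateral,
ventral); labels and regions are recorded as ground truth. The red
channel is this static template; the green channel scales each axon by a
calcium trace = 1 + smooth locomotor fluctuations (+ an optional
traveling wave: per-region Gaussian bumps of amplitude
`wave.amplitude` x the fluctuation amplitude, peaking `inter_region_lag`
apart in region order). Motion is a smooth rigid translation plus at
most three coarse sinusoidal displacement basis fields — deliberately
within the representational class of the smoothness-regularized
estimator; the generator warps the template by the negated true field so
that backward-warping each frame by the truth recovers the template
(exact for translations, first-order for the smooth non-rigid part). An
optional linear x gain emulates uneven illumination. Not emulated:
photon (shot) noise statistics, z-drift, occlusions, bleaching within a
trial, or anatomy that deforms non-smoothly — conclusions about
robustness to those must come from real data.

**Sensor traces** are piecewise-constant body-frame velocities pushed
through the documented forward geometry plus Gaussian noise; stationary
truth intervals are the spans where all true rates are zero.

**Arena trajectories** follow the stimulation protocol: forward walking
at `baseline_speed`, a linear ramp at `response_slope` to
`-backward_peak_speed` at each onset, then — so that the epoch minimum
is unique, as in real backward-walking bouts where speed partially
rebounds during continued stimulation — a linear recovery of
`recovery_fraction` (default 0.4) of the peak within the epoch, and
relaxation back to baseline in the first 2 s of the inter-stimulus gap.
Truth metrics apply the documented metric definitions to the noiseless
velocity samples. Heading is constant; wall contact and flips are
absent by default and can be injected for exclusion tests.

**Degradation series.** Disjoint circular ROIs bleach as
exp(-bleach_rate x (day-1)); in amputated flies the designated ROIs
additionally decay as exp(-amputation_decay_rate x (day-2)) from day 2
(the amputation day itself is unaffected). Day-to-day jitter is a
recorded random translation. Defaults: 15 days, 5 flies per group,
bleach 0.02/day, amputation decay 0.25/day.

## Problem sizes

The test suite and the acceptance script run the studies at reduced
frame sizes chosen as the package's desk-scale defaults: connective
movies 64 x 96 to 128 x 192 pixels with tens to ~160 frames per trial
(full acquisition scale, 480 x 736 / 352 x 576 after cropping, is
supported through the same specs); the caffeine study uses 3 flies per
condition with 7 trials each; arena sessions are full length (59 s at
80 fps); degradation runs the full 15-day, 5 + 5 fly design.

## Known limitations

- The optic-flow data term is brightness constancy only; intensity
  changes that are not motion (e.g. bleaching within a trial) would bias
  fields on real data.
- The sensor geometry matrix is a fixed idealization; real rigs need a
  calibrated matrix.
- The temporal denoiser is a linear local-average contract, not a
  learned model; it cannot exploit spatial structure.
- Translation-only registration of daily projections cannot absorb
  rotation or scale changes between sessions.
- With three flies per group, the exact Mann–Whitney test can never
  reach p < 0.05; the continuity-corrected normal approximation is used
  for those contrasts, exactly as in the original analysis, and its
  p = 0.040 under complete separation should be read with that caveat.
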