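# Methods

This note documents the models, conventions and defaults behind each
stage, the design choices made where the design was genuinely open, and
what the synthetic benchmark does and does not establish about real data.

## Data model and conventions

Movies are dense `(T, C, Y, X)` arrays of 16-bit unsigned counts. Frame
and channel indices are 0-based everywhere, including CSV output. Frame
`t` is acquired at `t * frame_interval_s`. Subpixel positions are
`(y, x)` floats with the origin at the *center* of the top-left pixel, so
a spot sitting exactly on pixel `(i, j)` has position `(i.0, j.0)`;
pixel membership in photometry is decided by pixel-center distance.
Physical calibration (pixel size, frame interval) is supplied explicitly
via config or function arguments, never read from TIFF tags, whose
dialects are unreliable. LIF and other vendor containers are rejected
with a pointer to TIFF conversion. Missing values (intensities at
unresolved gap frames) are written as empty CSV fields, never 0.

## Synthetic translation movies

The simulator generates the two-channel benchmark used throughout the
test suite: channel 0 carries each mRNA spot at constant unit intensity,
channel 1 its nascent-protein signal.

**Kinetics.** Ribosome initiations per mRNA are a Poisson process with
rate `ki` (default 0.04 1/s). Each ribosome advances deterministically at
`ke` codons/s (default 5) and leaves at the stop codon `L_total`
(default 2000). The normalized intensity is the summed fraction of
epitope probes each ribosome has translated, in units of one mature
protein. Default epitope layout: 10 probes uniformly spaced over the
first 10% of the ORF (an N-terminal tandem-epitope tag), giving a mean
probe position of codon 100 and an effective probe-to-termination length
`L_eff = 1900` codons — so the mean transit time, which sets the ACF
de-correlation time, is `L_eff / ke = 380 s`. A burn-in of one full
transit before frame 0 puts traces in steady state from the first
sample. Ribosomes are points (no exclusion: at ~15 ribosomes per 1900
codons steric effects are negligible) and elongation is deterministic
(per-codon rate noise is second-order for the transit-time statistics
measured here).

**Motion.** Spots perform reflected 2D Brownian motion with per-axis
step variance `2 D dt`. The benchmark default `D = 0.02 px^2/s` gives a
sub-pixel step per 5-s frame (0.45 px), emulating membrane-tethered,
near-static mRNA while keeping the tracking stage non-trivial. Initial
positions are drawn with a 12-px minimum separation.

**Rendering.** Each spot is a symmetric 2D Gaussian (sigma 1.3 px).
Signal amplitudes decay as `exp(-kb t)` with `kb = 0.001 1/s` per
channel; the camera background (100 counts) does not bleach. Poisson
shot noise and Gaussian read noise (sd 2) are applied, then the frame is
quantized to 16 bits. All randomness derives from one seed through
spawned generator streams, so a movie is bit-reproducible.

**Brightness calibration.** The unit-spot amplitude defaults to 150
counts, i.e. a peak signal-to-background-noise ratio of ~15 at t = 0,
decaying to ~2.4 — the conventional detectability limit — by the final
frame (1800 s of bleaching). This value was calibrated once so that
automated-threshold detection recovers most but not all of the 80 spots
when averaged over the whole movie (measured: ~74 per frame, recall
0.92, precision 0.98), reproducing the partial recovery a bleaching
movie exhibits in practice. A dimmer setting (SNR ~3 at t = 0) leaves
spots invisible for the last two thirds of the movie and is not a usable
benchmark condition.

**What the benchmark does not emulate:** cell-shaped backgrounds and
autofluorescence gradients, spot brightness heterogeneity beyond ribosome
statistics, mRNA birth/death, ribosome collisions or pausing, focus
drift, and 3D optics. Passing tests demonstrate correctness of the
algorithms under the stated noise model, not performance on arbitrary
real movies.

## Photobleaching

Bleaching is fitted as `I(t) = A exp(-kb t) + offset` on the per-frame
mean intensity of a region (whole frame, a mask, or a per-frame mask
following the spots), by nonlinear least squares initialized from a
log-linear regression; the offset initializes at the 1st percentile of
the frame means. The offset term absorbs the camera background, which
does not bleach; correction therefore rescales only the signal above the
offset, per channel, and clips to 16 bits (clipped-pixel counts are
recorded). A zero-variance movie returns `kb = 0` with a flag rather
than an error. Fitting region means rather than pixels matches the
physics (bleaching is a field-wide multiplicative process) and is robust
to shot noise. When measuring the decay of moving spots, use a
time-varying mask that follows them: a static mask conflates bleaching
with spots drifting out of the region (measured bias: ~3x on the
benchmark).

## Spot detection

The detector is a scale-normalized Laplacian of Gaussian (`-sigma^2 *
LoG`), matched to the expected spot sigma, followed by local-maximum
extraction with non-maximum suppression (default min separation 3 px)
and subpixel refinement by intensity-weighted centroid in a `4 sigma + 1`
window (the window minimum is subtracted so the background pedestal does
not pull the centroid). Gaussian fitting is deliberately deferred to the
quantification stage; the centroid is accurate to < 0.1 px on clean
spots and much cheaper per frame.

**Automated threshold.** Candidate thresholds form a 50-step geometric
grid from the median positive filter response to its 99.99th percentile.
Two established estimates are combined: (A) the elbow of the
spot-count-vs-threshold curve — the point farthest from the chord
joining the curve endpoints on normalized linear axes, which lands at
the base of the noise cliff; and (B) the plateau — the geometric center
of the flattest stretch of log counts after excluding the noise-saturated
region (counts within a factor 2 of maximum), where the count is
dominated by stable true spots. The returned threshold is the geometric
mean of A and B; both ingredients are recorded in metadata. On axes
choices: an elbow computed on log-log axes lets the faint tail corner
win and was rejected after measurement.

**Clusters.** A detection is flagged as a cluster (candidate aggregate)
when its connected above-threshold footprint exceeds
`cluster_multiplier` (default 3) times the nominal single-spot
footprint, which is measured from a noise-free calibration render at the
declared sigma whose brightness matches the median detected peak
response, thresholded identically. Footprint area was chosen as the
"size" notion because it is threshold-consistent and needs no extra fit.

## Tracking

Frame-to-frame linking is optimal bipartite assignment (minimum total
squared displacement) among pairs within the gate `max_disp_px`,
implemented with the Hungarian algorithm; a greedy nearest-neighbor
variant is available for comparison and is provably never better in
total cost. Track heads that miss a detection stay open for up to
`memory` frames and search within `max_disp_px * (gap + 1)`. Tracks
shorter than `min_track_len` (default 10 detections; correlation
analysis needs length) are discarded. Gap positions are not interpolated
in the track itself; the intensity stage decides (`skip` marks the frame
missing, `interp` measures at the linearly interpolated position).

MSD curves are time-averaged within tracks with pairwise deletion over
gaps; the ensemble diffusion coefficient comes from a pair-count-weighted
linear fit `msd = 4 D tau + b` over the first 4 lags (short-lag fits
minimize confinement and statistical bias), with a bootstrap-over-tracks
confidence interval and D clamped at 0.

## Intensity quantification

Disk-and-annulus photometry: `total` sums pixels within the disk radius
(default `ceil(2.5 sigma)`), background is the *median* of the annulus
(default 3 px wide, starting at the disk edge) — median, not mean, so a
neighbor in the ring cannot bias it — and `bg_sub = total - median *
disk_area`, floored at 0 in traces. SNR is peak-above-background over
ring standard deviation. Off-image windows are measured on the clipped
region and flagged. The `gauss` method fits a symmetric 2D Gaussian
(amplitude, center, sigma, offset) by least squares from moment
initialization and reports the analytic integral `A * 2 pi sigma^2`;
non-convergence (or sigma outside (0.3, patch/2) px) is a flagged
result, never an exception.

## Colocalization

Within a frame, spots from two channels are matched one-to-one by
minimum total distance with a hard gate (default 2 px, roughly one PSF
sigma plus localization error) — one mRNA owns at most one nascent
signal, so all-neighbors counting is wrong here. Track-level
colocalization summarizes per-frame matches: the colocalized fraction is
computed over co-resolved frames only, pairs reaching `min_fraction`
(default 0.5) are reported, and each track joins at most one pair (best
fraction wins, ties by smaller mean distance). The per-frame-then-
fraction convention was chosen over matching track-averaged positions
because it degrades gracefully when tracks overlap only partially in
time.

## Correlation analysis and kinetic rates

Per trace, `G_i(tau) = <dI(t) dI(t+tau)> / mu^2` with pairwise deletion
over gaps; the reported curve is the across-trace mean with its standard
error. Two normalization means are available:

- `ensemble` (default): `mu` is the grand mean of all retained traces.
- `per_trace`: `mu` is each trace's own mean, which removes spot-to-spot
  brightness variation but, on traces only a few de-correlation times
  long, subtracting the sample mean biases the ACF downward at long lags
  and drags the zero crossing in. Measured on the benchmark ensemble
  (1800-s traces, tau_c 380 s) the crossing lands ~20% early under
  per-trace normalization; ensemble normalization is unbiased there, so
  it is the default. Prefer `per_trace` only when spot brightnesses are
  strongly heterogeneous and traces are much longer than tau_c.

Zero-variance traces (and traces with fewer than 20 resolved points) are
excluded and counted; `g0_extrap` removes uncorrelated measurement noise
from the zero-lag amplitude by linearly extrapolating lags {dt, 2dt,
3dt} to zero, and both raw and extrapolated values are always reported.

**De-correlation time.** Two conventions are implemented. The default,
`linear_intercept`, fits a straight line to the central decay of G (lags
where G is between 20% and 80% of the extrapolated amplitude) and
returns its zero intercept; for the ribosome-transit ACF this estimates
the mean probe-to-stop transit time `L_eff / ke` directly, and for an
exactly linear G it equals the crossing to machine precision. The
alternative, `crossing`, returns the first interpolated zero crossing of
the mean curve; it is exact on clean triangular ACFs but, because the
epitope ramp makes the true ACF tangent to zero near the full transit
time, its sampling distribution at realistic ensemble sizes has a heavy
right tail (hundreds of seconds of scatter at n = 80), which is why it
is not the default.

**Rates.** `ke = L_eff / tau_c` (the user supplies `L_eff` in codons for
real constructs) and `ki = 1 / (g0 * tau_c)`, the Poisson-occupancy
relation (G(0) is the inverse mean ribosome load `ki * tau_c`).
Confidence intervals bootstrap over traces. Cross-correlation is
two-sided, normalized by the product of the channel means, and reports
the peak lag.

## Pipeline and reproducibility

Stages run in the fixed order simulate → bleach → segment → detect →
track → intensity → colocalize → correlate, driven by a strictly
validated YAML config (unknown keys are errors). The bleach stage fits
and corrects every channel by default (a single channel can be selected).
Detection and segmentation always run on the *raw* movie: bleach
correction cannot improve SNR but amplifies late-frame noise, which
destabilizes a single global threshold (measured on the benchmark: ~13x
more detections, precision collapse). Intensity traces are extracted
from the corrected movie so the correlation stage sees decay-free
signals; on the benchmark this full image-based pipeline recovers
G(0) ≈ 0.073, tau_c ≈ 411 s, ke ≈ 4.6 codons/s and ki ≈ 0.033 1/s from
the simulated (0.04, 5.0) truth. Every stage writes its
parameters into `metadata.json` along with the package version, seed and
timestamps; CSV outputs are byte-identical across reruns with the same
config and seed. A stage failure leaves a `FAILED` marker naming the
stage and keeps partial outputs.

## Problem sizes used in validation

The packaged benchmark (360 frames, 512x512, 80 spots) is exercised in
full by the acceptance checks (bleach-rate recovery, detection counts,
correlation kinetics). Unit and property tests run on scaled variants —
typically 40–64 frames, 128–160 px fields, 6–12 spots, and 80–400 traces
— chosen so each statistical assertion retains at least ~3-sigma
discrimination while the whole suite stays interactive.

## Known limitations

2D only (single-plane movies); single-exponential bleaching (no
bi-exponential or pixelwise models); symmetric Gaussian PSF photometry;
no Kalman/motion-model tracking and no track merging/splitting; no
deep-learning segmentation (import of externally computed masks is
supported); no model-based ACF fitting (the shape near zero is used only
through the linear intercept); distance-based colocalization only.
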