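# Methods

## The optical model behind the assay

The assay treats the camera as a photometer. A white tablet on a black
vessel floor is recorded from above at 10 frames/s; the mean grey value
(MGV) over a fixed region of interest is, to first order, proportional to
the bright area visible in the ROI, and that area is used as a linear proxy
for the amount of undisintegrated solid. This linearity is an assumption,
not a calibrated law: scattering from suspended fragments, gel
translucency and illumination drift all bend it in real recordings. The
package therefore anchors every recording to its own references
(background and intact tablet) rather than to absolute grey levels.

Both anchors are means over whole companion recordings, not single frames:
each reference is typically recorded for minutes at 10 Hz, and averaging
suppresses per-frame sensor noise by a factor of √N. The background MGV is
subtracted from the per-frame MGV *and* from the intact-tablet MGV, so the
0 % and 100 % anchors live on the same background-corrected scale; the two
conventions (correcting the 100 % anchor or not) only coincide when the
background is negligible, and using one scale for both is the
self-consistent choice. An assay whose background-corrected full-tablet
MGV is below a contrast tolerance (default 5 grey levels) is rejected
outright — a near-invisible tablet produces unstable ratios, not data.

% remaining is computed as `100 · ((MGV(t) − MGV_bg) / MGV₀)`, the ratio
formed before scaling so that the anchors are float-exact: the background
reads exactly 0.0 and the intact-tablet reading exactly 100.0. Values are
never clipped. Readings above 100 % are the optical signature of swelling;
readings slightly below 0 % are noise around an empty vessel, and both are
flagged per sample (`swelling` / `negative`) in the profile output.

## Canonicalization choices

Frames are canonicalized to 2-D grayscale on a 0–255 floating-point scale:
3-channel input is combined with ITU-R BT.601 luma weights (0.299, 0.587,
0.114), the de-facto default of common imaging software, and 16-bit input
is rescaled linearly by 255/65535. The time base is `frame_index /
frame_rate_hz`, 0-based, with container-embedded timestamps deliberately
ignored for determinism; decimation keeps every k-th frame while retaining
the original-index time base, so a decimated series is an exact
subsequence of the undecimated one. The ROI is user-supplied (a rectangle
in 0-based half-open pixel coordinates, or a mask image) and held fixed
across all recordings of an assay; automatic tablet segmentation is
intentionally out of scope.

## Profile analysis

Timepoint summaries report the replicate mean and the sample standard
deviation (n−1 denominator; 0 when n = 1) of the linearly interpolated
profile values. Linear interpolation at 10 Hz sampling introduces error far
below the noise floor and is reproducible, which matters more here than
higher-order accuracy. Smoothing (a centered moving average with a window
in seconds, shrinking at the recording edges) is off by default and, when
used, is recorded in the profile metadata; all validation runs are
unsmoothed.

Classification applies thresholds in a fixed decision order:

1. **swelling** — the profile sustains ≥ 105 % for at least 5 s, evaluated
   after a 5 s burn-in so the splash of medium addition cannot trigger it.
   The 105 % default sits well above the observed noise floors (hundredths
   of a percent for typical ROIs) yet far below the 120–135 % recoveries
   gelling formulations produce; the sustain requirement uses a sliding
   minimum over windows spanning the sustain duration.
2. otherwise the **endpoint** is the first time the profile drops to or
   below the completion threshold (default 10 % remaining) *and never rises
   above it again*. The default reflects that formulations plateauing at
   8–21 % are reported as incompletely disintegrated, so the boundary must
   sit near that range; it is configurable per call. Endpoints within 10 s
   are **instant**, within 30 s **fast** (the FDA limit), and any later
   endpoint **prolonged** — including endpoints past the 3 min
   pharmacopoeial bound, since the tablet did disintegrate completely,
   just slowly.
3. **partial** — no endpoint within the recording: residual material
   remains. A profile that never crosses the threshold and never sustains
   swelling falls here regardless of its final level; it is the residual
   category.

Raising the completion threshold can only move the endpoint earlier, a
monotonicity the test suite checks as a property.

The noise floor in percentage units is the standard deviation of a
background-only recording pushed through the full normalization; profile
changes smaller than about three noise floors should not be interpreted.

Condition comparisons use a Welch (unequal-variance) two-sided t-test
computed from summary statistics (mean, sd, n per group) with
Welch–Satterthwaite degrees of freedom. With n = 3 replicates and visibly
unequal group spreads, pooling variances is not defensible; Welch is the
conservative default. Stars follow the exact step function P ≤ 0.05 (*),
≤ 0.01 (**), ≤ 0.001 (***). When both groups have zero variance and equal
means, p = 1 by convention; zero variance with unequal means is rejected
as degenerate rather than reported as infinitely significant.

## The simulator

The simulator emulates the optical structure of the assay, not its
physics: a disc of intensity 220 on a background of 15 (the white-on-black
contrast of the real setup), recorded at 10 frames/s for 250 s, with
i.i.d. per-pixel Gaussian noise (default sd 2 grey levels, a plausible
consumer-sensor figure) added before clipping to [0, 255] and 8-bit
quantization — so the pipeline is always exercised on the canonical
quantized scale it meets in practice.

Ground truth is a closed-form kinetics curve R(t): first-order decay to a
plateau (`plateau + (100 − plateau)·e^(−k(t−lag))`), saturating swelling
(`100 + A·(1 − e^(−k(t−lag)))`), or a biphasic form (the decay curve minus
a slow linear tail, floored at 0). Before the lag — medium contact — every
model holds at 100 %.

Disintegration is rendered as **area shrinkage**: the disc radius scales
as √(R/100), so disc area, and hence the ideal ROI-MGV above background,
is proportional to R(t). This matches the photographic appearance of a
shrinking, fragmenting tablet footprint; swelling is the same mapping with
R > 100, area growth at constant intensity. An alternative intensity-fade
mode scales brightness at fixed geometry and yields the same ideal ROI-MGV
by construction. Disc edges are anti-aliased with a one-pixel linear ramp,
then each frame's total coverage is rescaled to the exact disc area πr² —
without this the ramp systematically over-covers by ~π/12 px² and leaves a
half-covered center pixel as r → 0, i.e. a tablet that never quite
vanishes. Configurations whose swollen disc would leave the frame are
rejected at construction.

Randomness is fully seeded: replicate r of a bundle draws from seed + r
(with a phase index decorrelating the background, intact-tablet and
disintegration recordings), and an identical configuration reproduces
every frame bit-for-bit.

What the simulator does *not* emulate — fragment advection, illumination
drift, translucent gel layers, heavier-tailed sensor noise, any effect of
temperature or medium volume (these are metadata labels only) — bounds
what passing tests mean: they demonstrate that the pipeline recovers a
known area-kinetics signal through the full imaging chain, not that the
linear MGV–mass proxy holds for any particular formulation.

## Problem sizes and numerical tolerances

Validation runs use a scaled-down geometry (disc radius 16 px in a 64 px
frame, ROI ≈ 40×40 px) while keeping the temporal protocol at full scale
(10 Hz, 200–250 s recordings); the ROI mean over ~1600 pixels already
averages per-pixel noise of 2 grey levels down to a ~0.05 % floor, so a
larger frame changes nothing essential. Noiseless end-to-end recovery is
accurate to ~0.13 percentage points at every frame (8-bit quantization and
edge discretization are the only error sources, against a 0.5 pp bound);
noisy three-replicate timepoint means recover the analytic curve to well
under 1 pp. MGV computation is required to match a brute-force masked mean
to 1e-9 grey levels, and the summary-statistic Welch test to match a
full-data reference within 1e-10 in p.

## Known limitations

- Video containers require an ffmpeg-backed imageio plugin; in its absence
  recordings must be supplied as ordered PNG/TIFF frame stacks (the fully
  supported path).
- The MGV–mass linearity assumption above; profiles from strongly gelling
  or strongly scattering systems measure optical footprint, not mass.
- The run log carries wall-clock timestamps and is excluded from the
  byte-determinism guarantee; all data artifacts (CSV/JSON/PNG) are
  byte-reproducible from identical configuration.
- Classification thresholds are operational conventions, not pharmacopoeial
  definitions; the completion threshold in particular must be chosen with
  the formulation's residual behaviour in mind, and results record every
  threshold used.
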