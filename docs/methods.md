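# Methods

This note documents the models and procedures implemented in `srtpipe`,
the defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical conventions that resolve ambiguities in the
underlying procedures.

## Task model and behavioral analysis

**Deadline model.** Each SRT trial draws a foreperiod FP from
{0.5, 1.0, 1.5} s (uniform by default), an internal deadline D, and a
detection+motor latency L, and releases the lever at min(D, FP + L).
Releases before the stimulus (D < FP) are premature; stimulus-triggered
releases are correct if L ≤ 0.6 s (the response window) and late
otherwise. Probe trials (10% by default) run the same race against a
stimulus that never arrives, so their hold durations share the
pre-stimulus structure of stimulus trials; they carry no outcome and are
excluded from all outcome ratios and from G(t).

The model itself does not prescribe distribution families for D and L.
The simulator defaults are shifted log-normals — right-skewed and
positive, matching the qualitative shape of empirical hold-duration and
RT distributions:

- deadline D: 0.2 s shift, log-median 1.7, log-SD 0.4 (median ≈ 1.9 s) —
  mostly beyond the longest foreperiod, as in a well-trained animal,
  yielding premature fractions near 0% / 3% / 25% for the three
  foreperiods;
- latency L: 0.1 s shift (latencies below 0.1 s are physiologically
  implausible for reactive responses and are excluded from analysis),
  log-median 0.2, log-SD 0.35 → median RT ≈ 0.3 s;
- poke latency on rewarded trials: log-normal, median 1.5 s;
- lesion effects are modeled as scale shifts of these laws
  (`lesioned_params`): deadline scale < 1 produces the
  compromised-waiting phenotype, poke scale > 1 the vigor deficit.

All behavioral event times are quantized to the 10 ms task clock; spike
times to 1 ms. Both resolutions round-trip exactly through the CSV
formats.

**Trial classification.** Stimulus-trial releases with latency in
(0, 0.1) s are labeled `subthreshold_reactive` and excluded from both RT
samples and premature counts: they are too slow to be deadline releases
timed before the tone and too fast to be reactions, so their status is
ambiguous. A switch (`include_subthreshold`) re-admits them to G(t) for
sensitivity analysis. Self-timing uncued trials are premature below the
foreperiod, correct within the 1 s reward window, late after.

**Anticipation function.** G(t) is computed on the 10 ms grid over
[0, max FP), half-open at the longest foreperiod; grid points whose
denominator (trials with FP strictly greater than t) is empty are
flagged undefined, never reported as 0. Counting is done in integer
clock ticks, so `hold ≤ t` at a grid point is unambiguous (the ≤
convention: a release *at* t has occurred by t). Because trials of an
elapsed foreperiod leave the numerator and denominator together, G is
non-decreasing within each foreperiod branch but may step down at a
branch edge in finite samples; in expectation every branch estimates the
same deadline CDF, which is why the sup-norm deviation from the
generative CDF shrinks with sample size (verified at n = 30,000 trials,
sup error < 0.03). The pre-to-post change in the integral of G is
computed by the trapezoid rule over the jointly defined grid, per
contiguous run.

**RT and outlier handling.** RT pools correct + late trials, windows to
[0.1, 2] s, then removes values more than k·1.4826·MAD from the median
(k = 10). The 1.4826 factor makes the MAD a consistent SD estimate under
normality — the convention of the common `rmoutliers`-style routines.
When MAD = 0, the cutoff collapses and only values equal to the median
survive: a constant sample is untouched, a lone deviant among ≥ 50%
ties is removed.

**Pooling.** Conditions pool whole sessions only: Pre walks backward
from the last prelesion session until every foreperiod exceeds 500
responses; Post_Early forward and Post_Late backward from the lesion
until 200. Incomplete pools are flagged with achieved counts. For
session-series metrics, an undersized postlesion session (< 50
responses; < 30 for retrieval durations) attaches forward, transitively,
to the first subsequent full-sized session.

**Hold-duration density and mode.** The density is a fixed-bandwidth
Gaussian kernel estimate (bandwidth 0.075 s — the kernel σ) evaluated at
0.05 s bin centers spanning [0, max + 4·bandwidth], truncated at 0
without boundary correction (holds are far larger than the bandwidth in
practice). The response-distribution mode is the center μ of
a·exp(−(t−μ)²/2σ²) fitted to that density by nonlinear least squares
over the full curve, initialized at the empirical peak. Recovery error
is < 0.02 s at n = 1,000 for generative modes at 1.14 and 1.48 s.

**Speeding classification.** Per rat, OLS of RT on FP (seconds, numeric);
the two-sided slope p-values across rats are thresholded at the BH
critical value (FDR 0.05); significant negative slopes are `speeding`,
positive `anti_speeding`. Rats with a single foreperiod level are
excluded with a warning.

## Neural analysis

**SDF.** Spike trains are convolved with a unit-area Gaussian
(σ = 20 ms, truncated at ±6σ) on the 1 ms grid; a single spike peaks at
1/(σ√2π) ≈ 19.95 Hz.

**Event warping.** Each trial's SDF is resampled segment by segment so
that press, stimulus, release, and poke align to the across-trial median
target times; the margins before press and after poke are copied
unwarped. Within a segment, target sample i maps to source position
i·s with s = (source span)/(target span) — the ratio is oriented
source-over-target so the index always stays inside the source segment,
whether the segment is compressed or stretched — and the value is
standard linear interpolation; integer positions return the source
sample exactly, so an identity warp is bit-exact. A warp followed by its
inverse returns a smooth trace within the O(dt²) interpolation bound.

**PETHs, ranking, epochs.** Warped trials are averaged, mean-subtracted,
and divided by the SD over the unit's full warped grid per foreperiod
condition (the normalization window is a package convention, exposed as
a parameter; a baseline-window alternative can be swapped in).
Zero-variance traces are flagged rather than z-scored. Units are ranked
by peak time on the long-foreperiod condition and that ranking is
applied unchanged to the short condition; ties break by earlier time,
then unit id. Epoch modulation is the mean |z| over Hold
(press→stimulus), Response (stimulus→release), and Poke (release→poke).

**PCA.** The time × unit matrix of z-scored PETHs is column-centered and
decomposed (full SVD). Variance fractions are non-increasing and sum to
≤ 1; projections are mutually orthogonal. Component signs are fixed by
orienting each component so its largest-magnitude unit loading is
positive; cross-region component correlations are reported sign-aligned
(|r|) by default because PCA signs are arbitrary.

## Kinematics

Trajectories live in an analysis space with y increasing upward (the
reader negates image-row y on request), so the reach apex is simply the
maximum-y sample (ties → earliest). Camera drift between sessions is the
integer shift maximizing normalized 2D cross-correlation against the
reference session (default: the first prelesion session); a weak peak is
logged. Paw reaches — not locomotor paths — are endpoint-aligned to the
set's mean endpoint before gridding, so landing scatter on the lever
does not deflate similarity.

Occupancy grids mark every cell crossed by the sampled polyline using a
supercover grid traversal (unlike Bresenham, corner-clipped cells are
not skipped, so 50 Hz sampling yields a connected band), then smooth
with a unit-sum 2D Gaussian whose σ is the "width" parameter
(25 px at the full 800 × 700 grid; the original procedure does not
disambiguate σ versus support width, so σ is exposed). Because the
kernel is normalized to unit sum, absolute dot-product scores are on an
implementation-defined scale; only ratios and orderings are meaningful,
and all checks use them. Similarity between conditions is the median
dot product over all unordered within-set or all cross-set pairs. Reach
speed is the polyline length from lift-off to apex divided by elapsed
time, in px/ms.

## Inference

Two-sample permutation tests shuffle pooled labels (statistics: median
difference for RTs, proportion difference for premature indicators, mean
difference otherwise); paired tests flip signs of differences with the
mean as statistic. When the arrangement count (C(n, n₁) or 2ⁿ) is at
most 20,000 the test enumerates exactly and reports the exact tail
fraction; otherwise Monte-Carlo p-values use the add-one convention
(1 + #{|T*| ≥ |T|})/(n_perm + 1), which is never zero and keeps the test
valid at finite permutation counts. Null calibration: the empirical
type-I rate at α = 0.05 over 1,000 null replicates lies in
[0.035, 0.065], and p-values are super-uniform. The BH step-up reports
the largest sorted p with p₍ₖ₎ ≤ (k/m)q as the family's critical
threshold (0 when none qualifies); significance is p ≤ critical.
`pooled_t_summary` computes the pooled-variance two-sample t and
df = n₁ + n₂ − 2 from printed means/SDs/counts. Repeated-measures ANOVA,
Tukey HSD, and rank-sum comparisons are deliberately delegated to
standard library calls in report scripts and are not part of the tested
core.

## What the simulators do and do not emulate

The generators reproduce the statistical structure the analyses assume:
the deadline race with interleaved foreperiods and probes, Gaussian
self-timed holds with a 10% cue fraction, spiking whose rate profile is
anchored to each trial's *actual* event times (so RT jitter propagates
into the spike trains), and curved constant-speed paths with isotropic
per-sample noise. They do not emulate: sequential effects and
motivational drift across a session, non-Poisson spiking (bursting,
refractoriness), electrode drift or unit loss, tracking dropouts, or
lesion physiology beyond scale shifts of the deadline and poke-latency
laws. Tests passing on simulated data therefore validate the estimators
and their implementations — not claims about biological variability that
only real recordings can exercise.

## Problem sizes and numerical conventions

Simulated checks use sizes chosen to make their statistical bounds
sharp at desk scale: 30,000 trials for deadline-CDF recovery, 200 trials
per unit for warp-template recovery, 1,000 replicates for permutation
calibration, 12 reaches per condition (a typical session's tracked
yield) for similarity orderings, n = 1,000 for mode recovery. Degenerate
inputs fail loudly with typed errors (`SchemaError`, `ValidationError`,
`ParameterError`); empty RT pools warn and return empty samples; missing
event times are empty CSV fields, never sentinels. All generators are
bit-reproducible given (parameters, seed).
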