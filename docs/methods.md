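# Methods

This note documents the models, rules and numerical choices behind
`pawkit`, and what its synthetic-data generators do and do not emulate.

## Conventions

Frame indices are 0-based; times are milliseconds relative to stimulus
onset (onset = 0 ms), so an event first seen at frame `f` has latency
`(f − onset_frame)·1000/fps`. Images use the video convention: origin
top-left, y increasing downward; left/right are as viewed in the image.
The pixel scale for the 400 fps whole-body camera defaults to 0.32 mm/px.
CSV files are comma-separated UTF-8 with `.` decimals.

## Withdrawal detection from FTIR traces

Baseline statistics are the mean and **population** SD (divisor N) over the
pre-stimulus window (by default all pre-onset frames; at the standard
500 ms baseline and 125–500 samples the N vs N−1 choice is immaterial, but
it is fixed for bit-reproducibility).

Detection rules on the post-onset segment:

* `sd5` — responded iff any sample ≤ `mean − 5·SD` (inclusive).
* `strict` — responded iff any sample ≤ `min(0.8·mean, mean − 4·SD)`;
  used where false positives are costly (rare-response protocols).

Latency is reported at the frame grain (no sub-frame interpolation): it is
the time of the first frame meeting the criterion. With a degenerate
baseline (SD = 0) the `sd5` threshold collapses onto the mean; a
`RuntimeWarning` is raised and a *strict* drop below the mean is required,
so constant traces (and constant pixels in latency maps) never register
spurious zero-latency responses.

**Rise time (20–80 %)** is the time between the trace first falling 20 %
and first falling 80 % of the way from the baseline mean to the post-onset
minimum, with linear interpolation between frames (the 20/80 crossings
rarely coincide with a frame). A 10 ms linear ramp therefore reads 6 ms.

**Extent** is `100·(mean − min)/mean` over the post-onset window (the full
post-onset epoch by default); ≥ 75 % decrease is a *full* response,
responding trials below that are *partial*. The minimum that anchors both
extent and the rise-time levels is taken after a short running median
(kernel 5, the radius-2 median filter also offered as trace
preprocessing): the raw minimum of ~10³ plateau samples is biased low by
the noise extreme value, while a running median leaves monotone segments
and clean plateaus untouched, so noise-free examples are unaffected.

**Quality control** rejects trials with baseline mean < 3 (too dim), with
baseline mean/SD < 23 (too noisy; the ratio direction is configurable —
see "Design choices"), or with detected latency ≤ 10 ms (too fast to be
stimulus-evoked).

**Pixel latency maps** apply the same rule independently per pixel
(per-pixel baseline statistics) and count, per pixel, frame pairs whose
absolute change exceeds the binarization threshold. No-response pixels are
NaN in float outputs and −1 in integer exports.

## Binarized motion energy

For each retained pair of consecutive frames, a pixel scores 1 if its
absolute 8-bit change is **strictly greater** than the threshold (a change
of exactly the threshold is noise) and 0 otherwise; the per-pair sum is the
motion-energy trace. Thresholds default to 5 gray levels for the 40 fps
whole-body view and 7 for the 400 fps view. Laser-affected frames are
removed before pairing, so pairs may span a gap.

Normalization subtracts the baseline-pair mean; the sign convention makes
more-motion positive so the peak is a maximum (the alternative subtraction
order inverts the trace and makes "peak ≥ k SD" unintelligible). The
400 fps variant divides by the pixels-per-frame count first. A trial is
retained if its peak normalized motion energy reaches 5 baseline SDs
(optionally within a 100 ms post-stimulus time-locking window); movement
onset is the first crossing above 10 baseline SDs and the bout ends at the
first return below that level. Baseline SD is computed over baseline frame
pairs of the normalized trace (mean subtraction does not change the SD, so
the open question of raw vs normalized counts for the low-rate recordings
is moot). A zero baseline SD triggers a warning and an absolute fallback
(any motion above baseline).

## Pose post-processing and kinematics

Filtering removes a point when (1) its likelihood is below 0.95; (2) it
jumps ≥ 10 px from the **previous retained** point and the next frame does
not return to within 10 px of the pre-jump position (a sustained jump is
movement, not a glitch); (3) it falls on one of the stimulation frames.
Removed points become NaN and are never interpolated — downstream
operations propagate gaps. Filtering is idempotent.

Trial QC fails when more than 10 % of labels (over the analysis parts,
excluding the by-design-removed stimulation frames) are missing or when
more than 10 frames were mislabeled. "Mislabeled" is operationalized as
the frames flagged by the jump rule, plus an optional caller-supplied
manual list — this keeps the published manual criterion automatic and
testable while preserving the manual pathway.

The stimulated limb is identified from laser pixel saturation: the count
of saturated pixels inside a 60×60 px window around each hind-paw label is
compared between 7.5 ms before and 5 ms after stimulus onset (rounded to
the nearest frames; 3 frames before and 2 after at 400 fps). Ties or
absent saturation return `unknown` for a manual call.

Movement onset of a part: baseline position is the mean over 10
consecutive pre-onset frames; onset is the first post-stimulus frame
displaced ≥ 0.5 px from baseline whose subsequent 10 frames all move
≥ 0.5 px/frame. Frames with missing data cannot qualify, so onsets inside
the removed stimulation window are not observable — the earliest
detectable onset at 400 fps is 12.5 ms.

Egocentric alignment translates coordinates so the baseline tail base is
the origin and reflects x when the stimulated paw's baseline x is negative
(stimulated paw on the right by convention); left/right parts are
relabeled stimulated/contralateral. Alignment is translation + optional
reflection only — no rotation, since the retained body-axis variability is
part of the pose structure the PCA should see; a rotation flag exists for
sensitivity analyses. The 12-dimensional feature vector is (x, y) of nose,
stimulated digits/heel, contralateral digits/heel and tail base.

Head yaw is the angle of the tail-base→nose vector minus its baseline
circular mean, wrapped to (−180°, 180°], sign positive toward the
stimulated side; the window summary is the **circular** mean (arithmetic
and circular means agree to < 0.1° at the dispersions involved, but the
circular mean is the defensible default for angles).

## Statistics

**PCA** is mean-centered SVD; component signs are fixed by making each
component's largest-magnitude loading positive, so repeated fits are
identical. An optional 80:20 pseudo-random split reports the variance the
training components explain in both subsets. Trajectory projections score
each frame against the fitted components; time-course explained variance
is the per-component share of pooled variance.

**Trajectory directions** are the angles of PC1–PC2 displacement vectors
across a 35–115 ms window; dispersion is the circular SD
`sqrt(−2 ln R̄)` with R̄ the mean resultant length. The `parts` shuffle
control permutes (x, y) pairs within each trial before projection,
destroying part identity while keeping each trial's coordinates.
Zero-displacement trials are excluded and counted. Directions use PC1–PC2
only by default (a 3-D option exists but adds little once PC3 is mostly
orientation).

**Balanced hierarchical bootstrap**: per replicate, M mice are sampled
with replacement (M = number of mice), then k trials with replacement from
each sampled mouse, with k = round(mean trials per mouse) by default —
equal contribution per mouse with a resample close to the original size;
k is configurable since equal contribution alone does not pin it down. The
statistic (median, or mean for motion-energy magnitudes) is computed on
the pooled M·k values; the estimate is the mean of the replicate
distribution and the SE its SD. With one mouse and k equal to its trial
count the scheme reduces to the standard one-level bootstrap. Default
10 000 replicates, fully vectorized.

**Sum rule**: `P(X ≥ 1) = 1 − (1 − p)^n`, strictly increasing in both
arguments; `n = 1` returns `p` exactly (the naive expression loses one
ulp). **Pulse-matched latency** maps a trial latency to (pulse index,
residual): index is the largest i with `i·isi ≤ latency`, capped at
`n_pulses − 1`.

**Friedman's test** uses the tie-corrected rank chi-square with
df = conditions − 1; an all-tied table returns statistic 0 and p 1 rather
than the 0/0 the textbook formula produces. Dunn's pairwise comparisons
use `z = |R̄_i − R̄_j| / sqrt(k(k+1)/(6n))` on mean ranks with two-sided
normal p-values and no further adjustment by default (configurable through
the statsmodels multiple-testing methods). **Regression fits**: `linear`
(with Pearson r), `loglog` (log y on log x; power law), and `lognormal`
operationalized as y on log x — with the log y on log x coefficients also
reported when y is positive, since the parameterization is not unique.
R² is computed in the transformed space of the fit.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code; their defaults are the study
conditions of the recordings they emulate: 1000 fps local / 400 fps
whole-body cameras, 1.5 s trials with a 500 ms baseline, 8-bit baselines
around 100 with i.i.d. Gaussian noise of SD 2 (clipped to [0, 255];
stacks rounded to integers, traces kept unrounded), withdrawal latencies
near 30 ms with 2 ms mouse-level and 5 ms trial-level spread, 4 ms 20–80 %
rise times, 90 % extents, a 29 ms stimulated-paw movement onset, and a
20° head-yaw effect toward the stimulated side.

FTIR falls are truncated-logistic by default (steepness a = 4 over the
fall interval; sigmoidal like real contact loss) with a linear option for
analytic rise-time tests. Ground-truth latency is defined as the time at
which the *noise-free* trace crosses `mean − 5·noise SD` — the moment the
programmed drop becomes detectable — and is snapped to the frame grid,
making the ±1-frame closed-loop tolerance well-posed regardless of fall
shape. Mouse effects are additive Gaussian shifts on latency location.

Whole-body stacks contain a static random texture plus per-frame sensor
noise (SD 1.5) and a textured disc that translates at 2 px/frame from a
programmed frame; a saturated disc at the stimulated paw during the
stimulus frames supports limb-detection tests. Pose cohorts draw per-trial
initial poses (whole-body translation SD 4 px, per-part conformation SD
2 px), per-trial movement directions (SD 25° around part-typical
directions), magnitudes (lognormal, trial SD 0.2 plus an optional
mouse-level scale), tracking jitter (SD 0.1 px) and likelihood dropout;
paw speed is 2.5 px/frame (~1 m/s at 0.32 mm/px), comfortably above the
0.5 px/frame persistence floor. The nose ramps to its yaw plateau in
7.5 ms starting at 12.5 ms (just after the stimulation frames) and then
drifts radially so the persistence rule can time its onset; the fast ramp
keeps the 300 ms window mean within ~1° of the plateau.

Pulse-train outcomes trigger each pulse independently with probability p;
a responding trial's latency is its first triggering pulse's onset plus a
per-pulse reaction time drawn from a truncated normal (location 60 ms,
scale 15 ms, support [0, 95] ms). Capping the support below the shortest
inter-stimulus interval of interest makes every response attributable to a
unique pulse, which is exactly the construction under which pulse-matched
latency distributions superimpose across frequencies.

None of the generators attempt biomechanical realism: there is no paw
texture or fur, no postural dynamics beyond the programmed movements, no
correlated sensor noise, and no tracker failure modes beyond likelihood
dropout and single-frame glitches. Passing closed-loop tests therefore
demonstrates that the analysis recovers what its rules define on signals
with the programmed statistics — not that the rules are optimal for any
particular recording rig.

## Design choices and degenerate inputs

* The printed QC criterion "baseline SD/mean ≥ 23" is arithmetically
  implausible for 8-bit data with mean ≥ 3 (it would demand SD ≥ 69);
  it is implemented as an SNR floor, mean/SD ≥ 23, preserving the evident
  intent of rejecting noisy baselines. The ratio direction is a
  configuration switch for anyone wanting the literal reading.
* Latency is measured from pulse **start** (not end) for all pulse
  durations.
* The jump rule compares against the previous **retained** point when
  earlier points were removed (the alternative — previous raw frame —
  cannot flag glitches adjacent to dropout).
* Withdrawal extent windows default to the full post-onset epoch.
* Sentinels: NaN in float outputs, −1 in integer exports.
* Problem sizes in tests and the acceptance script (200-trial closed
  loops, 50 oracle stacks, 80-trial pose cohorts, 100 × 2000-replicate
  bootstrap coverage runs, 10 000-replicate single estimates) are chosen
  so each check is statistically meaningful at desk scale.

## Known limitations

* AVI/MP4 decoding requires an imageio video backend; the toolkit's native
  exchange formats are NPY/NPZ stacks and per-frame PNG directories.
* No rotational egocentric normalization (by design; flag available).
* No mixed-effects models or Bayesian inference; the hierarchical
  bootstrap is the only nesting-aware estimator.
* The head-yaw sign convention is undefined when the baseline nose lies
  exactly on the left-right axis through the tail base; such frames keep
  the raw sign.
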