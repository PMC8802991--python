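# Methods

`mealscope` implements the computational core of a laboratory platform for
measuring eating behavior in real time: meal microstructure from a concealed
plate balance, dwell-time coding of wearable eye-tracker gaze against dynamic
areas of interest (AOIs), the reliability and method-agreement statistics used
to validate a human coding protocol, portion-size memory scoring by the method
of adjustment, and blood-draw timing compliance. This note records the models,
the defaults, and the choices made where the design was genuinely open.

## Meal microstructure

The balance reports plate weight every 2 s at 0.1 g resolution. A *bite* is a
weight decrease between two consecutive readings of at least `min_bite_g`
(default 1.0 g). The scale resolves 0.1 g, but sub-gram dips are
indistinguishable from residual table vibration, so the default sits an order
of magnitude above the resolution; it is configurable, and mass-conservation
checks run at 0.1 g. Weight *increases* (a touched plate, pressure against the
table) are never corrected silently: each becomes an artifact flag, and a
session with more than `artifact_budget` flags (default 3) is marked invalid.
Validity gates only set flags — computed numbers are never altered.

Cumulative intake is C(t) = a·t² + b·t + c fitted by least squares to
(initial weight − weight(t)). The *deceleration rate* is |2a| in g/s², with
the sign of `a` reported separately (negative `a` means eating slows toward
the meal end). The instrument convention behind this definition is the classic
cumulative-intake-curve quadratic; the fit uses every retained sample, not
only bite events, because the staircase between bites carries information
about pauses. Blood draws are removed as *exclusion windows*: samples inside
a window are dropped but retained samples keep their original timestamps, so
curvature stays physically interpretable; the meal duration is the raw span
minus the merged window lengths, and the eating rate (g/min) is total consumed
over that effective duration.

Degenerate inputs: fewer than 3 distinct time points make the quadratic fit
an error; a zero effective duration makes the eating rate an error; an empty
bite list makes the mean bite size an error rather than a silent NaN.

## Gaze quality control and fixation classification

*Gaze capture* is the percentage of samples with valid coordinates; a
recording passes at ≥ 80 % by default, a threshold appropriate for
within-subject designs where saccades plus tracker dropout rarely exceed
20 % of samples.

Fixations are classified with a velocity-threshold (I-VT) filter. Angular
velocity is computed *point-to-point*: each valid sample carries the velocity
of the segment from it to the next valid sample (the last sample uses its
backward segment), scaled by `deg_per_px` (small-angle approximation over the
plate region; default 0.05 °/px). Assigning the forward segment — rather than
a symmetric central difference — keeps a stationary sample that abuts a
saccade inside its fixation, so noiseless streams recover scheduled fixation
durations exactly; a central difference smears saccade velocity one sample
into every following fixation. Runs of samples below the velocity threshold
(default 30 °/s, the conventional default of commercial I-VT filters — the
device's own setting is not published) become candidate fixations; candidates
shorter than `min_fixation_ms` (default 100 ms, below which saccades are
rarely exceeded in duration) are discarded. A fixation's end time extends one
sample period past its last member sample, so 25 samples at 50 Hz form a
500 ms fixation. Invalid samples never contribute to centroids; a gap between
valid samples longer than 1.5 sample periods plus `gap_fill_ms` (default 0,
i.e. no interpolation) breaks a fixation.

## Dynamic AOI assignment and dwell

AOI polygons are keyframed; lookup is a left-closed step function (the latest
keyframe at or before t), matching a manual workflow of re-drawing AOIs every
10 s as food disappears. A fixation spanning a keyframe boundary uses the
polygons at its onset, the frame a manual coder codes by.

Assignment intersects a circular gaze marker (default radius 20 px at a
1920 px scene) with each polygon, using the overlap shares of the *covered*
marker area. In `manual` mode the top label wins only if it exceeds a
dominance threshold (default 60 % of covered area); otherwise the fixation is
`mixed`. Both the radius and the threshold are explicit assumptions: the
coding manual's visual guide is qualitative. In `agm_compatible` mode —
emulating automatic gaze mapping, which cannot code mixtures — only rice,
vegetables, meatballs and the plate border are eligible, the maximum overlap
always wins, and exact ties break deterministically in that label order.
`recode_for_agm` maps manually coded output onto the AGM vocabulary:
fixations inside declared fork intervals take the food AOI behind the fork,
and `mixed` fixations take a declared most-likely AOI. Because mixed mass is
redistributed but never destroyed, total dwell over coded AOIs is conserved
across modes. Proportional dwell divides each AOI's fixation time by the
total over the included labels and sums to 100 % at machine precision before
any presentation rounding.

## Reliability and agreement statistics

For k AOI pairs rated by two raters (N = 2k ratings), the one-way
sum-of-squares ICC treats each pair as a group:

    MS_b = SS_between/(k−1),  MS_w = SS_within/(N−k)
    ICC  = (MS_b − MS_w)/MS_b

This is the one-way random-effects, average-measures form (ICC(1,k));
`pingouin`'s ICC(1,k) is used as an independent cross-check in the tests, not
as the implementation. A negative ICC (MS_w > MS_b) is reported as computed,
with a warning, rather than truncated to zero.

The Reliable Change Index uses SEm = SD_ref·√(1−ICC), Sdiff = √(2·SEm²), and
RCI = (x₂−x₁)/Sdiff, with |RCI| ≥ 1.96 flagging disagreement beyond
measurement error. SD_ref defaults to the between-group SD of the sample
(√MS_b), under which SEm reduces algebraically to the within-group SD — an
identity asserted numerically in the tests. On the packaged 14-pair fixture
(values printed to 1 decimal) this yields SEm = 2.16, Sdiff = 3.06 and
reproduces the full printed RCI column to 3 decimals; the fixture's ICC is
0.9649 and its between-group SD 11.52, close to but not exactly the published
0.97 and 11.74, which were computed from unrounded source data.

Bland–Altman limits of agreement are mean difference ± 1.96 SD with a
Shapiro–Wilk normality gate on the differences: when the differences are
non-normal at α = 0.05 the limits are flagged not applicable but still
reported. `paired_compare` applies the same gate to choose between the paired
t test and the Wilcoxon signed-rank test; all-zero differences are reported
as degenerate with p = 1. These standard tests are delegated to `scipy.stats`.

## Portion ladders and recall scoring

A portion ladder starts at a one-tablespoon gram anchor and grows in exact
energy increments (20 kcal default; 5 kcal for low-energy-dense foods), with
grams per step = step_kcal/energy density, truncated at the ~80 %-plate-fill
mass and at 110 images. Recall accuracy is reported both as the ratio
100·recalled/actual and as the signed percent error (their difference is
exactly 100); downstream comparisons use the signed error. Snapping a served
amount to the ladder introduces at most half a step of quantization error.

## Timing compliance

Deviation is *target − actual* (negative = late draw). The summary reports
mean, SD, a t-based 95 % CI (the t distribution is the conservative choice at
n per cell of a few hundred; the alternative normal CI differs negligibly),
right-closed lateness bins at 60/120/180/300 s, and the proportions within 1
and 2 minutes of target. Draws overlapping the meal convert to exclusion
windows for the microstructure stage.

## Synthetic data

The generators emulate the study conditions rather than idealized inputs, and
every stream is deterministic given a seed (each generator derives its own
substream from the user seed plus a fixed offset, so one stream never shifts
another).

- **Meals**: 630 s, 400 g initial load, C(t) = 0.85·t − 0.00055·t² (≈30 g/min,
  deceleration |2a| = 0.0011 g/s²), bites ~N(3.5, 0.8) g on a 2 s grid with
  0.1 g rounding, 10 % per-sample pause probability, optional zero-mean scale
  noise. The meal ends with a final partial mouthful completing the planned
  intake, so total consumption matches the model curve rather than stopping
  one random bite short. What it does *not* emulate: plate repositioning
  artifacts, sauce transfer, utensil weight events.
- **Gaze**: scheduled fixations at AOI centroids with pixel jitter, linear
  sweeps between them, Bernoulli dropout, optional slow positional drift
  standing in for head movement. It does not emulate blinks as structured
  dropout, vestibular-driven smooth pursuit, or scene-camera distortion.
- **Rater tables**: two columns derived from true dwell proportions by
  independently misclassifying a fixed fraction of each AOI's mass onto the
  other AOIs (Dirichlet-weighted), then renormalizing; rate 0 gives ICC = 1
  and the expected ICC decreases monotonically in the rate.
- **Extraction logs**: normal timing deviations (default −13 ± 54.4 s) and
  log-normal durations around a mean (default 80 s).

Because the generators share the analysis code's data contracts but none of
its algorithms, parameter recovery (generator → analyzer) is a meaningful
end-to-end check — while passing it shows correctness of the implementations
under these statistical assumptions, not robustness to the messier artifacts
of real recordings listed above.

## Recovery tolerances and problem sizes

Recovery checks run at desk scale: 200 seeded meal replicates (~316 samples
each), 100 random gaze streams of ≤ 500 samples for the oracle-equivalence
check, 10 000 differences for Bland–Altman coverage, 1 000 random tables for
the SEm identity, and 295 extraction events (59 sessions × 5 post-meal
draws). For microstructure recovery the recovered mean over 200 replicates
must lie within **two between-session SDs** of the generating value: eating
rate and bite size are unbiased to well within one SD, while the deceleration
estimate retains a ~0.2 % staircase-quantization bias (≈0.4 SD) inherent to
measuring curvature from 3.5 g bite increments — a property of the
measurement process, not of the fitting code, whose exactness on noiseless
streams is asserted separately to 1e−9.

## Known limitations

- The marker radius, mixed-zone dominance threshold and I-VT velocity
  threshold are assumptions exposed as configuration, not published device
  settings.
- Multi-rater (> 2) ICC variants, ICC confidence intervals, and mixed-effects
  modelling of trial outcomes are out of scope.
- The package consumes already-mapped gaze coordinates and AOI polygons; it
  performs no video decoding, feature matching, or fork detection.
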