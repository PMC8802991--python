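# mealscope

Analysis toolkit for laboratory studies of eating behavior that combine a
concealed plate balance (a Universal Eating Monitor), a wearable eye-tracker,
blood sampling, and an image-based portion-memory task. It is written for
researchers in ingestive behavior and psychophysiology who need to turn the
raw streams such a platform produces — weight–time series, gaze samples,
AOI polygon timelines, rater coding tables, extraction logs — into the
standard derived measures, and to validate their coding protocols with the
field's reliability statistics.

## What it computes

**Meal microstructure.** From a weight stream sampled every 2 s at 0.1 g:
bites (consecutive weight decreases ≥ a threshold), mean bite size, meal
duration, eating rate (g/min), and the deceleration rate as |2a| of a
least-squares quadratic fit C(t) = a·t² + b·t + c to cumulative intake.
Blood-draw pauses are subtracted as exclusion windows; weight increases are
flagged as artifacts, and sessions exceeding an artifact budget are marked
invalid.

**Gaze processing.** Gaze-capture QC (valid-sample percentage, gated at 80 %)
and I-VT fixation classification: point-to-point angular velocity against a
threshold (default 30 °/s) with a 100 ms minimum-duration cut-off.

**Dynamic AOI dwell.** Fixations are assigned to keyframed AOI polygons by
circular-marker overlap, in either manual-protocol emulation (with `mixed`
zones) or AGM-compatible coding (rice/vegetables/meatballs/border only), and
summarized as absolute and proportional dwell per AOI over any window.

**Reliability & agreement.** One-way sum-of-squares ICC for paired ratings,

    ICC = (SD_b² − SD_w²) / SD_b²,   SEm = SD·√(1 − ICC),
    Sdiff = √(2·SEm²),               RCI = (x₂ − x₁) / Sdiff,

with |RCI| ≥ 1.96 flagging rater disagreement beyond measurement error;
Pearson's r; Bland–Altman limits of agreement (mean difference ± 1.96 SD,
with a normality gate); and paired t / Wilcoxon comparisons.

**Portion memory.** Method-of-adjustment portion ladders in exact energy
increments (20 kcal, or 5 kcal for low-energy-dense foods, up to 110 images)
and recall scoring as percentage accuracy and signed percent error.

**Timing compliance.** Blood-draw deviations (target − actual), t-based 95 %
CIs, lateness bins, within-1/2-minute proportions, and the share of mealtime
occupied by draws.

A seeded synthetic-data module generates all four stream types with the
statistical structure of real sessions, so the full pipeline is testable
offline; `mealscope.pipeline.run_session` orchestrates QC → exclusions →
microstructure → fixations → dwell → compliance for a session, and
`run_cohort` tallies invalid outputs across sessions.

## Worked example

A two-rater reliability analysis of the packaged coding-protocol table
(14 AOI pairs across two videos, % fixation time per AOI):

```python
from mealscope.io import load_rater_reliability_fixture
from mealscope.reliability import icc_oneway, rci_analysis, pearson_r

table = load_rater_reliability_fixture()
fit = icc_oneway(table)
rci = rci_analysis(table)
print(f"Pearson r = {pearson_r(table):.3f}")
print(f"ICC (one-way, SS method) = {fit.icc:.3f}")
print(f"SD_between = {fit.sd_b:.2f}, SD_within = {fit.sd_w:.2f}")
print(f"SEm = {rci.sem:.2f}, Sdiff = {rci.sdiff:.2f}")
for p in rci.pairs[:3]:
    flag = " *" if p.significant else ""
    print(f"{p.group:>14}: x1={p.x1:5.1f}  x2={p.x2:5.1f}  RCI={p.rci:6.3f}{flag}")
```

prints

```
Pearson r = 0.932
ICC (one-way, SS method) = 0.965
SD_between = 11.52, SD_within = 2.16
SEm = 2.16, Sdiff = 3.06
        rice:A: x1= 28.8  x2= 32.2  RCI= 1.113
   meatballs:A: x1=  7.3  x2= 14.0  RCI= 2.193 *
  vegetables:A: x1= 14.3  x2= 14.9  RCI= 0.196
```

The ICC of 0.965 says the two raters' percentages agree almost as well as
repeated measurements of the same video could; the one starred RCI (meatballs,
calibrated-plate video, |RCI| ≥ 1.96) is the single AOI where they disagree
beyond measurement error, so that AOI's coding instructions deserve revision.

Microstructure of a simulated ten-minute meal:

```python
from mealscope.synthetic import MealSimParams, gen_weight_stream
from mealscope.microstructure import summarize

series = gen_weight_stream(MealSimParams(seed=42, scale_noise_sd_g=0.05))
r = summarize(series)
print(f"duration = {r.meal_duration_min:.1f} min, bites = {r.n_bites}, "
      f"mean bite = {r.mean_bite_g:.2f} g")
print(f"eating rate = {r.eating_rate_g_min:.1f} g/min, "
      f"deceleration = {r.deceleration_g_s2:.4f} g/s^2")
```

prints

```
duration = 10.5 min, bites = 88, mean bite = 3.60 g
eating rate = 30.2 g/min, deceleration = 0.0011 g/s^2
```

The same operations are available from the shell, e.g.
`mealscope irr --table rater_table.csv`,
`mealscope microstructure --weights W.tsv --exclusions E.csv`,
`mealscope run --config session.yaml --out report.json`.

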