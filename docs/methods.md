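# Methods

This note documents the models, conventions and numerical choices behind
`gaitsym`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
demonstrate about real motion-capture data.

## Coordinate and timing conventions

Lab frame: `x` anterior (direction of travel), `y` to the participant's
left, `z` vertical up, ground nominally at `z = 0`. Trials walked toward
−x are rotated 180° about `z` on load (a proper rotation, so the frame
stays right-handed and the operation is idempotent). Frame indices are
0-based; intervals are half-open. Marker files are expected at 100 Hz;
nothing in the code assumes that rate except the defaults.

Occlusion gaps are filled by linear interpolation up to 100 ms (10 frames
at 100 Hz); longer gaps reject the trial, because interpolated events are
not trustworthy at the 10-ms scale the pipeline targets. Passes shorter
than 2 s are rejected as well.

## Filtering

Raw positions are smoothed with a Butterworth low-pass filter applied
forward and backward (`scipy.signal.sosfiltfilt`, reflective padding of
3× the effective order). The design is an order-2 section at 6 Hz; the
dual pass squares the magnitude response — effective order 4, zero phase
lag, gain exactly 0.5 at the design cutoff:

    |H(f)|ᵈᵘᵃˡ = 1 / (1 + (f/6 Hz)⁴)

No cutoff-warping correction is applied: 6 Hz is taken as the design
cutoff of the single-pass section, the convention under which "gain ½ at
cutoff for the dual pass" holds analytically and is verified by the
tests. Derivatives (central differences, one-sided at the ends) are
always taken on the *filtered* signal.

A property worth knowing: the zero-phase Butterworth kernel has a
vanishing second moment (its response expands as 1 − (f/f_c)⁴ + …), so
locally quadratic signal segments pass through with no bias in value or
extremum location. The synthetic generator exploits this (below); it is
also why event timing on real, smooth marker data survives 6 Hz
filtering largely unshifted.

## Event detection

Detection uses only vertical heel/toe kinematics, so it works overground
without force plates:

* **Heel contact** — local minima of filtered heel height, at least
  0.4 s apart (`refractory_s`; caps cadence at ~150 steps/min), whose
  height lies within 15 mm of the trial's 5th-percentile heel height
  (`heel_band_m`) and whose preceding 50 ms mean vertical velocity is
  negative (the heel is descending). Minima within one refractory
  interval of the trial edges are discarded: boundary filter transients
  can fake a touchdown and partial cycles are dropped anyway.
* **Toe-off** — within each same-foot heel-contact-to-heel-contact
  cycle: the stance toe height is the median of the cycle's early-stance
  third (robust to marker noise); the swing rise is the first frame
  exceeding it by 5 mm (`toe_rise_m`) after the toe has first settled
  below that level; the toe-off is the last upward zero crossing of toe
  vertical velocity at or before the rise.

A toe-off is reported only when bracketed by two same-foot heel
contacts, so incomplete leading/trailing cycles disappear without a
special case. Step intervals are assembled from strictly alternating
left/right contacts; a same-foot repeat (missed contralateral detection)
drops the affected step with a logged warning rather than patching it.

All thresholds are exposed in `EventConfig` / the pipeline config file.
On synthetic trials the detector locates every steady-state event within
±1 frame noise-free and ±2 frames at 1–2 mm RMS marker noise, with
sensitivity and precision 1.0 (events matched within 30 ms).

## Gait parameters

* **Step length / width** — anterior / absolute mediolateral heel-to-heel
  displacement at the leading foot's heel contact. The absolute value
  keeps width nonnegative; crossing steps, rare at preferred pace, fold
  onto positive widths. Backward steps (nonpositive length) are dropped
  with a warning as detection faults.
* **Double support** — leading heel contact to trailing-foot toe-off, in
  seconds.
* **MFC** — within 20–80 % of each swing (toe-off to next same-foot heel
  contact), the lowest *interior local minimum* of toe height minus a
  ground reference, reported in cm. The window excludes toe-off and
  landing artifacts; "lowest local minimum" (not the plain window
  minimum) rejects monotone descents that have no true clearance event.
  Two references are supported: `midstance_median` (per-foot median toe
  height over mid-stance thirds — a foot-flat proxy that absorbs the
  static offset of a shoe-mounted marker) and `absolute` (raw height,
  for data whose floor is exactly z = 0, e.g. the synthetic cohort).
  Swings shorter than 10 frames or without an interior minimum are
  skipped with a warning (≈1 % of synthetic swings, short-swing cases).

Per subject, parameters are summarized side-stratified and pooled, with
the sample (n−1) SD as the intra-subject variability measure; spatial
and temporal step parameters stratify by leading foot, MFC by swinging
foot. Subjects with fewer than 30 step cycles (`min_steps`) are flagged
and excluded listwise from cohort statistics — the same inclusion rule
the acquisition protocol it models uses. Whether the non-SI summary
columns should pool sides or use a dominant side is genuinely open; this
package pools both sides and documents it here.

## Symmetry Index and GHQ-12

SI = |R − L| / ((R + L)/2) × 100 %, the inter-limb difference normalized
by the inter-limb mean. It is symmetric in its arguments, scale
invariant, zero iff R = L, and bounded by 200 % on nonnegative inputs.
Applied to each parameter's side means and side SDs it yields 8
asymmetry features. The printed form of this index is typographically
ambiguous in parts of the literature ("(R−L)(R+L)×0.5"); the
implementation follows the standard reading — the ×0.5 belongs to the
denominator mean — which is the only reading with the documented
[0, 200] range.

GHQ-12 totals use bimodal (0-0-1-1) scoring: item codes {0,1} (the
"disagree"/healthy pole) score 0, codes {2,3} score 1, totals 0–12.
Item-polarity reversal for positively worded items is assumed already
encoded in the stored codes; the package applies one uniform rule and
does not guess per-item polarity.

## Synthetic cohort generator

The generator is an *event-schedule* simulator, not a biomechanical
model: realism is supplied exactly where the detectors need it, and
ground truth is exact by construction.

**Per trial.** Per-step parameters (step time, step length, step width,
double support, per-swing MFC) are drawn from per-side normal
distributions and clipped to physiologic ranges; the event timeline is
quantized to the frame grid (so true event frames are integers); foot
placements are sequential (each lead heel lands `step_length` ahead of
and `step_width` lateral to the trailing heel — this makes per-step
spatial truth exact, at the cost of a slow lateral drift when widths are
asymmetric, which no pipeline stage uses). Marker curves are monotone
cubic (PCHIP) interpolants through control points: flat stance holds,
sigmoid swing advances with gentle arrival tails, a heel-rise/swing-peak
heel profile, and the classic double-peak toe trajectory whose mid-swing
local minimum is the programmed clearance, placed at 55 % of swing and
snapped to the frame grid. Every contact, toe-off and clearance minimum
is embedded in a locally symmetric *parabolic* neighborhood (±40–90 ms),
which — by the vanishing second moment noted above — makes the 6 Hz
zero-phase filter preserve both the event times and the minimum values;
the swing-tail geometry (late peak height/time, valley half-width)
scales with swing duration so short swings keep an interior minimum.
Optional white marker noise is added last. Defaults describe a healthy
older-adult cohort at preferred pace: step length 0.657 ± 0.036 m, width
0.121 ± 0.030 m, double support 0.099 ± 0.019 s, MFC 1.667 ± 0.447 cm,
step time 0.55 s, 36 steps per trial (clearing the 30-cycle inclusion
rule), 100 Hz.

**Per cohort.** Each subject carries a standard-normal latent
mental-health burden m. For every parameter, the relative side asymmetry
of the mean is δ = δ₀ + β·m + ε and of the stride-to-stride SD is
γ = γ₀ + β_sd·m + ε′, realized as R = v(1+δ/2), L = v(1−δ/2). Baseline
asymmetries δ₀ (5.9–25.7 % across the four parameters) are set at the
scale reported for cohorts of this kind; couplings default to β = 0.10
(with β_sd 0.40–0.62) so that the *measured* SI–GHQ correlations come
out at r ≈ 0.50–0.64 for n = 126 — the reported scale — after the
attenuation caused by estimating side means and SDs from ~17 steps per
side. The SD couplings for double support and MFC are higher than the
rest precisely because their SD estimates carry the most measurement
noise (timing quantization, clearance extraction). GHQ items are
independent Bernoulli draws with agree-probability logistic in m; the
intercept −2.5372 and slope 1.4436 were solved numerically so totals
have mean 1.563 and SD 2.080, the published cohort calibration target.
Setting all β to zero (`CohortSpec.null()`) gives an exact null in which
asymmetry exists but is independent of GHQ. Ages are N(66.2, 8.38²) and
sex is drawn at the 96 F/30 M cohort proportion, both uncoupled.

All randomness flows from a single seed through numpy `SeedSequence`
spawning (one child stream per subject), so cohorts are bit-reproducible
and any subject can be regenerated in isolation.

**What the synthetic validation does not show.** The generator has no
soft-tissue artifact, no marker mislabeling, no curved or interrupted
walking paths, no gait-initiation/termination transients (trials begin
and end mid-steady-state), white rather than colored marker noise, and
stylized (if physiologically scaled) trajectory shapes. Passing the
recovery and calibration tests therefore demonstrates the internal
consistency and statistical calibration of the pipeline, not the
field accuracy of the event detector on pathological or noisy real
recordings — that requires force-plate or instrumented-walkway ground
truth.

## Cohort statistics

Pearson correlations (two-sided p from the exact t transform on n−2 df)
of each of the 16 features against the GHQ total, in the canonical
report order (per parameter: mean, SI mean, SD, SI SD). No
multiple-testing correction by default, matching common practice for
this table; `fdr=true` switches the significance flags to
Benjamini–Hochberg. OLS (statsmodels, with intercept) regresses the GHQ
total on a configurable predictor set; the default — 16 gait features
plus age, 17 predictors — reproduces the (17, 108) F-test
degrees-of-freedom structure at n = 126. Which 17th predictor the
original analyses of such cohorts used is not generally stated, so the
set is config-overridable. Rank-deficient designs raise an error naming
the dependent columns. Welch's unequal-variance t (Satterthwaite df) is
provided for group contrasts such as sex effects.

## Problem sizes and runtime

Default validation sizes, chosen to keep the whole suite and the
acceptance script at about three minutes combined on one CPU: 36-step
trials (~20 s of walking, 2 000 frames), 20-seed event-detection sweeps,
126-subject cohorts, and 20 replicates per calibration arm (null and
coupled). The statistical conclusions are insensitive to these sizes;
they were fixed once and are stated here so results are reproducible.

## Known limitations

* The event detector is a single fixed algorithm; treadmill protocols,
  shuffling gait or pathological foot-strike patterns may need different
  thresholds (all are config-exposed, none auto-tune).
* Step width's absolute value cannot represent true crossover steps.
* The MFC ground reference assumes either a foot-flat mid-stance
  (`midstance_median`) or a calibrated floor (`absolute`); neither
  models shoe-sole compression.
* GHQ item responses are modeled as conditionally independent given the
  latent score — adequate for calibrating totals, not for item-level
  psychometrics.
* The cohort model couples mental health to asymmetry only; pooled means
  and SDs are uncoupled by design, so the generator cannot reproduce
  reported *mean-level* associations (e.g. wider steps or lower
  clearance with worse scores).
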