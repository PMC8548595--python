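# Methods notes

This document records the model, the numerical choices, and the design
decisions behind `dyadgaze`, in the order the pipeline runs.

## Scene and coordinate conventions

All geometry lives in a fixed right-handed frame: metres, y up, origin
at the centre of the tabletop surface.  The two agents sit across the
table along the z axis (nasions at z = ±0.70 m, 0.45 m above the
table); the three 10 cm task cubes lie in a row along x at the table
midline, 30 cm apart; a 5 cm start cube sits near each agent's right
hand.  Any consistent frame would do — the pipeline only ever uses
relative geometry — but one had to be fixed and documented.

The gaze origin is a single cyclopean point per agent, coincident with
the nasion.  Binocular vergence and per-eye origins are out of scope.

## AOI semantics

* **Face** is an angular criterion: a look is on the partner's face
  when the gaze ray is within `face_radius_deg` (default 7.5°) of the
  partner's nasion.  The radius is configurable, so narrower
  (eye-region-only) re-analyses are a config change, not new code.
* **Hand, body, cubes, start** are solids hit-tested by ray
  intersection.  The hand box (10 × 20 cm, square cross-section) is
  re-posed every frame to start at the wrist and extend toward the
  index fingertip; since recordings carry only the fingertip marker,
  the wrist is reconstructed by stepping 20 cm back from the fingertip
  toward the agent's shoulder (nasion − 25 cm in y).
* **Precedence.**  The face test wins outright (it is angular and can
  co-occur with any box hit).  Among boxes, the nearest entry point
  along the ray wins — this makes occlusion behave correctly, e.g. a
  cube in front of the pointing hand is labelled as the cube.  Exact
  entry-distance ties fall back to hand > cube > start > body.
  Every sample gets exactly one label; `other` means nothing was hit,
  and invalid tracker samples are forced to `other` and barred from
  forming looks.

## Event segmentation

**Point onset.**  Velocity is estimated from the native 120 Hz
fingertip stream by central differences with a centered 3-sample
moving average.  A centered (odd) window is used deliberately: a
trailing window would phase-shift the speed estimate by half a sample
and bias every threshold-crossing time late.  The onset is the
earliest sample at which the speed *toward the target* (the projection
of velocity onto the fingertip→target direction) reaches 5 % of the
trial's maximum of that quantity, restricted to the contiguous
supra-threshold segment that actually ends within 10 cm of the target —
so preparatory twitches and feints toward other locations never
trigger it.  Plain speed magnitude is available via
`events.speed_mode: magnitude` since the directional reading of
"speed towards the object" is an interpretation; the projected form is
the default because it makes motion away from the target ineligible by
sign alone.  On minimum-jerk reaches the detector sits within one
120 Hz sample of the closed-form 5 % crossing (the crossing solves
30τ²(1−τ)² = 0.05 · 1.875 at τ ≈ 0.0592 of the movement duration).

**Looks.**  Per-sample AOI labels are run-length encoded.  `other`
runs no longer than `gap_bridge` (default 50 ms) flanked by the same
AOI are bridged (blink/dropout tolerance); genuine looks at a
different AOI are never bridged over.  Runs shorter than
`min_look_duration` (default 50 ms, three gaze samples) are discarded.
Both thresholds are config-exposed because no dwell criterion is
canonical; the defaults are the shortest durations that cannot be
produced by single-sample noise at 60 Hz.  Looks are half-open
[start, end) intervals.

## Trial labelling

* **Congruency** scans the initiator's looks backwards from the onset.
  Only cube and face looks participate; hand/body/start/other looks
  are transparent.  Last qualifying look = target cube → congruent;
  non-target cube → incongruent; face preceded by a target-cube look →
  uncharacterizable (gaze-point congruency is undefined for the
  target→face sequence).  A face look preceded by a *non-target* cube
  is classified incongruent by default (`face_after_nontarget`
  switches this to uncharacterizable) — the uncharacterizable class is
  reserved for the target→face pattern.
* **Overt attention** is true when a responder face look contains the
  onset instant, using a closed right endpoint so a look ending exactly
  on the onset sample still counts; `overt_window_s` widens the test to
  a look-back window (default 0).
* **Eye contact** requires the two agents' face looks to overlap by at
  least one gaze sample (configurable) inside the search window.  The
  window opens when the trial-start mutual-gaze handshake ends — the
  first moment neither agent is on the partner's face — because every
  trial *begins* with enforced mutual gaze, and counting the handshake
  would label essentially 100 % of trials as eye contact.  The window
  closes at point onset.
* **SRT** is the start of the responder's first target-cube look whose
  interval extends past the onset, minus the onset, in ms.  Responses
  at or under 100 ms are excluded as anticipatory (including target
  looks already under way at onset); responses over 3000 ms as not
  immediate; absence of any target look is its own exclusion reason.
* **Screening** drops error trials (point at a non-target cube) and
  trials whose eye-calibration validity is strictly below 0.90
  (validity exactly 0.90 is retained).  Error and calibration reasons
  take precedence over SRT-based reasons; every excluded trial carries
  exactly one reason and screening is idempotent.

## Statistical model

The response is a power-transformed SRT.  The transform is selected by
a Box-Cox profile-likelihood scan over λ ∈ [−2, 2] (401 grid points)
on all analysable SRTs at once, then snapped to log10 (λ≈0), square
root (λ≈0.5) or identity (λ≈1) when λ̂ is within 0.25 of the anchor;
otherwise the raw power transform is kept.  One transform is used for
all strata so stratified estimates stay on one scale.  Note that the
transform decision is only well identified when the data are visibly
skewed: for near-symmetric positive data the profile is flat and λ̂ is
noisy, which is why the selection tests use clearly skewed synthetic
data (squares of a normal with coefficient of variation 0.2, and a
log-normal).

The model is

    f(SRT) ~ congruency + (1 | pair/subject) + (1 | trial)

with congruency coded so b > 0 means incongruent-slower.  Subjects are
nested in pairs (unique subject codes); the trial factor is the
within-session trial index shared across pairs, crossed with the pair
hierarchy, capturing order effects.  statsmodels' `MixedLM` expresses
this as variance components in a single group (`vc_formula` for pair,
subject and trial; no free random-effects covariance), fitted by
maximum likelihood — ML rather than REML because the likelihood-ratio
comparison of models with different fixed effects requires it.  On one
frozen dataset the fit matches lme4's `lmer(..., REML=FALSE)` to four
decimals in b, SE, logLik and all four variance components (test
`test_matches_lme4_frozen_values`).

*Convergence ladder.*  If the saturated structure fails to converge
(or yields non-finite standard errors), the trial term is dropped,
then the pair level, and the rung actually used is reported in the
result (`random_structure`) and in every output file.

*Inference.*  Fixed-effect p-values use a Wald t with a residual-df
approximation (observations − fixed effects − random-intercept
levels); the `df_method` field flags this, since a
Satterthwaite-style df is not available in statsmodels.  In simulation
this test is well calibrated (type-I ≈ 5 % at 8 pairs × 20 trials over
1000 replicates), while rejecting on the LRT p at these sizes is
slightly anticonservative (~8 %); the package reports both.  The
model-comparison χ² equals 2·ΔlogLik with 1 df; the *evidence ratio*
exp(ΔlogLik) = exp(χ²/2) is reported alongside because "the model fits
k times better" is a likelihood-ratio statement, numerically different
from the χ² statistic, and the two are easy to conflate.

## Synthetic dyad generator

The simulator emulates the task structure the analysis assumes: each
pair completes 54 trials, 27 per participant as initiator, targets
balanced across the three cubes within each initiator (9/9/9),
initiator displays of three even numbers with the 6 on the target and
mixed odd/even responder displays, in seeded random order.

Per trial it scripts: a 0.4 s mutual-gaze handshake; an initiator
scanpath over the cubes (dwells uniform on 150–400 ms) whose final
pre-point fixation realises a drawn congruency class (congruent with
`p_congruent` among characterizable trials, target→face with
`p_uncharacterizable`); a minimum-jerk reach (0.8 s) whose analytic
5 %-of-peak crossing is the ground-truth onset; a responder who scans
cubes, is on the initiator's face at onset with `p_overt_attention`,
and first looks at the target one SRT after onset; and, with
`p_eye_contact`, an explicit 150 ms mutual-gaze episode mid-search.
Gaze is emitted at 60 Hz with isotropic angular jitter
(`gaze_noise_deg`, default 0.5°), hand at 120 Hz.  Anticipatory
(< 100 ms) and slow (> 3000 ms) responses, pointing errors, and
low-calibration trials are injectable at configurable rates to
exercise every screening rule.

SRTs are drawn from
Normal(`srt_base` − benefit·[congruent ∧ overt], `srt_sd`) plus pair,
subject and trial random intercepts, truncated at 120 ms.  Defaults:
base 675 ms, benefit 56 ms, residual SD 150 ms — the regime the
analysis is designed for, with the benefit conditional on overt
attention so the stratified dissociation is a generative fact the
pipeline must recover.  The random-intercept SDs (pair 40, subject 50,
trial 25 ms) are choices: plausible magnitudes that leave the marginal
SD near the 140–180 ms range typical of such data while giving each
level enough variance to be recoverable in parameter-recovery tests.
`p_congruent = 0.51`, `p_overt_attention = 0.60`,
`p_eye_contact = 0.0408` and `p_error = 0.02` set the behavioural
rates at the values the analysis context reports.
`simulate_trial_table` exposes the same distributional layer without
stream synthesis, for inference calibration studies.

*What the generator does not emulate* — and hence what passing tests
do not show about real data: head motion (nasions are static), eye
blinks and tracker dropout (validity is constant within trials),
saccade dynamics (gaze teleports between dwells), scanpath strategy
differences across individuals, the reported target-position
dependence of congruency (the middle cube attracting more congruent
gaze), and any correlation between a participant's congruency rate
and their partner's face-looking rate.  Two structural side-effects
are worth knowing: (1) the *realized* eye-contact rate exceeds
`p_eye_contact` because the target→face sequence combined with
responder overt attention mechanically produces mutual gaze before
onset (the scripted episodes plus this overlap give roughly 10 % at
the defaults) — the task structure genuinely affords this, and ground
truth is computed from the scripted intervals so label recovery is
unaffected; (2) simulated SRTs are normal, not right-skewed like real
reaction times, so Box-Cox on simulated data tends to keep the
identity scale whereas skewed empirical data selects √SRT.

## Numerical and degenerate-input choices

* Ray–box tests use the slab method; axis-parallel rays outside a slab
  are forced misses, rays starting inside a box have entry distance 0.
* A table of identical SRTs (zero variance) returns b = 0, t = 0,
  p = 1 rather than attempting a singular fit.
* Strata with fewer than two congruency levels, fewer than two pairs,
  or too few rows for transform selection raise an explicit
  insufficient-data error; the pipeline reports these per stratum
  instead of aborting.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical seeds reproduce
  sessions and reports byte-for-byte.

## Problem sizes used in validation

The oracle sweep checks 10,000 random ray configurations against a
dense-marching geometric oracle; onset detection is checked on 100
random reaches; label recovery on 10 noiseless sessions; type-I
calibration on 1000 replicates of a reduced 8-pair × 20-trial design
(chosen so the full calibration fits comfortably in a routine test
run); the power/dissociation check on 40 replicates at the full
26-pair × 54-trial size; and variance-component recovery on 20
replicates at 50 pairs.  `scripts/acceptance.py` runs the complete
raw-stream pipeline on one 26-pair study.

## Known limitations

* Fixed-effect p-values approximate the reference df; exact
  Satterthwaite/Kenward-Roger df would require a different backend.
* The trial random effect models order effects shared across pairs; a
  per-session trial effect is indistinguishable from residual noise in
  this design (one observation per trial) and is deliberately not
  parameterised that way.
* The wrist reconstruction for the hand AOI assumes a straight
  forearm-to-shoulder line; with real motion capture the wrist marker
  should be used directly.
* Gap bridging operates on AOI labels, not on tracker events; a long
  blink inside a look longer than `gap_bridge` splits the look.
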