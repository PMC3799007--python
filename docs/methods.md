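# Methods

`pstpupil` simulates and analyzes pupillometric studies of adaptive
processing-speed training built on the useful-field-of-view (UFOV)
paradigm.  This note documents the models, their parameters, the
numerical conventions, and the choices made where the underlying design
leaves room.

## Task model

Each trial presents a fixation cue for 506 ms, a stimulus for a variable
duration *d*, a full-screen white-noise mask for 1000 ms, and an
unspeeded memory probe, so the probe onset falls at 1506 + *d* ms from
cue onset.  All intervals are half-open `[onset, offset)`.  Four task
levels graduate the attentional demand: level 1 asks only for a central
car/truck identification (2AFC); levels 2–4 add a simultaneous
peripheral localization target at one of 8 locations equally spaced on a
circle 5.7° from fixation; level 3 surrounds it with easily rejected
triangle distractors; level 4 uses target-like distractors.  The angular
offset of the peripheral ring is not part of the design; we fix location
0 at 12 o'clock with clockwise indexing.  Geometry stays in degrees of
visual angle — nothing is rendered, so no pixel conversion exists.

Test phases (baseline and posttest) hold *d* = 200 ms and cycle the task
level 1, 2, 3, 4 every `set_size` trials; the standard configuration is
5 cycles of 25-trial sets, i.e. 500 trials.  The 50/50 car/truck split is
enforced exactly within each set via a seeded shuffle (a per-trial
Bernoulli alternative is what `assign_stimuli` draws); both satisfy the
published proportion, the balanced version deterministically.

## Staircase

Training blocks start at task level 1 and 200 ms on the duration ladder
306, 259, 200, 153, 106, 82, 59, 35, 24 ms.  Every fourth trial the
central and peripheral responses of the preceding four trials are
counted individually (so a level-2 window holds 8 responses) and the
windowed accuracy is compared with strict thresholds: above 75% the task
gets harder, below 37.5% easier, otherwise unchanged; exact 75% (6 of 8)
and exact 37.5% (3 of 8) therefore leave the task unchanged.  At the
ladder extremes a harder/easier step converts into a one-level task
change that preserves the current duration; level 4 saturates at 24 ms
and level 1 at 306 ms.  Duration and level never move in the same check,
and window counters always reset, so checks use disjoint windows.  For
level-1 windows (4 responses) the 37.5% boundary is unattainable; the
strict thresholds still apply (1/4 → easier, 2/4 → unchanged).  Each
training block re-starts the staircase (per-day reset is a config
switch).  The analyzer counts missing responses as incorrect; the
simulated observer always responds, so this path is exercised only by
external data.

## Simulated observer

Per-response accuracy is a logistic psychometric function of
log-duration,

p(d) = g + (1 − g − λ) · logistic(β · (log d − log θ_level)),

with guessing floors g = 0.5 (central 2AFC) and 1/8 (8-location
localization), lapse rate λ, slope β, and level-specific thresholds
θ.  Defaults: θ = 15/20/24/30 ms for levels 1–4, β = 3, λ = 0.10.  This
places 200-ms test accuracy at a lapse-limited ~90% — young adults on
this task perform near ceiling, in the low-80s to low-90s percent — while
keeping thresholds near the bottom of the duration ladder, which is the
only calibration under which simulated trainees progress to task 4
during adaptive training, as real participants did.  Training multiplies
thresholds by `training_shift` (default 0.7); during training the
effective shift interpolates linearly from 1 with completed blocks, a
simple practice model.  Response time is a truncated normal
(mean 0.95 s, sd 0.25 s, floor 0.2 s; only mean RT is analyzed), with a
posttest practice factor 0.94 applied to both groups.

## Pupil generator

Eye streams are produced at one sample per ms from cue onset to probe
onset.  Pupil diameter in arbitrary units (au) is

pupil(t) = gain · (B · (1 + A_level/100 · k(t)) + ε_t),

with baseline B = 1000 au, Gaussian sample noise ε (sd 2 au, mirroring
the ~0.2% relative resolution of a video tracker at mid pupil size; an
order-of-magnitude emulation, not physiology), a log-normal
session-specific gain (sd 10%), and a task-evoked kernel k(t): a
smoothstep rising from 200 ms after stimulus onset over 300 ms and then
exactly 1.  Because the rise completes before the analysis window for
every ladder duration (24 + 500 > 500 ms), the analysis reads only the
plateau and the kernel's shape is immaterial to every reported contrast;
with noise and blinks disabled, injected amplitude contrasts are
recovered by the full pipeline to machine precision.  Luminance is
constant by construction (equiluminant mask), so no light-reflex term
exists.  Gaze follows central fixation with 0.05° jitter, Poisson
saccades (1 Hz, 30-ms transitions, valid samples) and Poisson blinks
(0.1 Hz, 150 ms, invalid samples with pupil = 0).

Default evoked amplitudes (% of baseline) are 0/1.0/1.1/3.17 for levels
1–4 before training, so the expected percent-change contrasts from task
2 are ≈ +0.1 (task 3) and ≈ +2.1 (task 4) — the magnitude regime of the
load effects such studies report.  The trained group's posttest map
(1.0/0.283/0.939 for levels 2–4) flattens the load response toward the
task-2 level, emulating more efficient resource allocation; training
days interpolate linearly between the two maps, which produces the
decreasing within-training task-4 − task-2 trend.  Controls keep the
baseline map at both phases.

No per-subject variance for pupil effects is published anywhere we can
anchor to, so the dispersion defaults — per-subject amplitude traits
(sd 1.5 points per level), per-session amplitude scatter (sd 1.0 point),
per-subject threshold (log-sd 0.2) and RT (sd 0.1 s) offsets — are
chosen to produce group-level t and F statistics of realistic magnitude,
and make no claim of fidelity.  What passing tests show is therefore
that the measurement and inference chain is correct and unbiased under a
plausible generative model; they cannot validate the generator against
real eye-tracker data, which also contains drift, hippus, foreshortening
and luminance artifacts that the generator deliberately omits.

All randomness flows from one master seed through keyed `SeedSequence`
streams per subject, phase, block and trial, so a study regenerates
bit-identically and independently of processing order.

## Measurement pipeline

Only fixation samples are analyzed (eye movements bias measured
diameter).  Fixations are re-derived with a dispersion-threshold (I-DT)
detector — maximal runs of valid, clock-contiguous samples whose
dispersion (x-range + y-range) stays ≤ 1.0° for ≥ 100 ms; vendor
software originally did this step, so the algorithm choice is ours and
is validated against generator ground truth (boundaries within ±10 ms of
programmed saccades).  Blink samples split runs and never enter any
mean.  The window of interest is the 500 ms before probe onset (the
equiluminant final 500 ms of the mask).  A trial's measure is the mean
pupil over samples lying inside both the window and a fixation
(sample-weighted; a per-fixation-mean alternative sits behind
`AnalysisConfig.per_fixation_means` since the original aggregation order
is unstated) and is missing when no such sample exists — exclusions are
logged per trial, never silent.  Task-level means are unweighted means
over non-missing trials (trials are the experimental unit; unequal
fixation coverage should not reweight them).  Percent change from task 2
is 100 · (m_t − m_2)/m_2 with the task-2 row identically 0; it is
undefined (an explicit error) without a positive task-2 mean.  Task 1
engages focused rather than broad attention and is excluded from
summaries by default.  The normalization is exactly invariant to any
session-wide rescaling, which is why the arbitrary-unit gain never
matters.

## Statistics

The design is a balanced split-plot: Group (trained/control, equal n)
between subjects, Time (pre/post) and Task (2/3/4) within, one value per
subject × cell.  `mixed_rm_anova` computes the classical sums-of-squares
decomposition: Group is tested against subject-within-group; each within
effect and its Group interaction against the matching
effect × subject-within-group stratum.  With 10 subjects per group this
yields the characteristic df pattern (2, 36) for Task-type effects and
(1, 18) for Group × Time.  Unbalanced or incomplete data raise an error
— nothing is approximated or imputed silently.  No sphericity correction
is applied by default (Greenhouse–Geisser sits behind a flag), and
post-hoc paired t tests are uncorrected for multiplicity; both choices
match the reporting conventions of the literature this mirrors and are
flagged here deliberately.  The follow-up to the Group × Time
interaction is a pooled-variance two-sample t (df = n₁ + n₂ − 2) on each
subject's (post − pre) change of the (task 4 − task 2) contrast.
Within-subject error bars use Cousineau normalization (remove the
subject mean, add the grand mean) with Morey's √(M/(M−1)) correction;
they are exactly invariant to per-subject additive offsets.  Baseline
ANOVAs use subject-level observations (one value per subject × task),
consistent with the df conventions above.  A single-group design is
accepted (the between row is skipped), where the two-level within-effect
F reduces exactly to the squared paired t.

Degenerate inputs are handled explicitly: identical values give F = 0
with p = 1; a zero-variance error stratum under a nonzero effect yields
an infinite statistic with p = 0 and a warning.

## Workflow and problem sizes

`run_study` executes the full chain at the standard design (10 per
group, 500-trial test phases, six training days × two 375-trial blocks)
and reports the group table (pupil percent change to 2 decimals,
accuracy to whole percent, RT to 2 decimals), the ANOVA battery,
post-hoc and follow-up tests, within-subject error bars, and the
per-training-day task 4 − task 2 trend computed from the first block of
each day (the whole-day alternative is a config switch; the same
percent-change normalization is applied during training as at test).
Because the staircase rushes capable observers past task 2, days with
fewer than 4 usable trials in either task are flagged low-n rather than
silently averaged.  Unit and property tests run on scaled-down designs
(2–5 subjects per group, 8–40-trial sessions) because every quantity
they check is either exact or a mean whose precision the scaled size
already saturates; the acceptance script runs the full default design.
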