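# pstpupil

Simulation and analysis of **task-evoked pupillometry for adaptive
processing-speed training** studies.

Processing-speed training (PST) is a computerized intervention built on
the useful-field-of-view (UFOV) paradigm: on every trial the participant
identifies a briefly flashed central car/truck and, at higher task
levels, simultaneously localizes a peripheral target among distractors.
An adaptive staircase shortens the stimulus duration (306 → 24 ms) and
raises the task level as performance improves.  Because pupil diameter
under constant luminance indexes the attentional resources a task
recruits, recording the eye at 1000 Hz during such a study lets one ask
whether training makes resource allocation more *efficient*: after
training, does the pupil still dilate more for the hard task than for
the easy one?

This package implements the complete computational apparatus of such a
study, end to end, exercised on synthetic participants:

* the UFOV trial structure and the fixed 500-trial test schedule
  (levels cycling 1,2,3,4 every 25 trials at 200 ms);
* the dual-response training staircase — performance checks every 4th
  trial; windowed accuracy > 75% → harder, < 37.5% → easier, with
  duration/level transitions saturating at Task 4 × 24 ms;
* a synthetic-data module: psychometric observers
  (logistic in log-duration, guessing floor, lapse ceiling) and 1000-Hz
  pupil/gaze streams with a load-dependent task-evoked dilation,
  session-specific arbitrary-unit gain, saccades and blinks;
* the measurement pipeline — I-DT fixation detection, restriction to
  the 500 ms before probe onset (the equiluminant tail of the mask),
  per-trial and per-task means, and percent change from Task 2
  (the Task-2 mean is defined to be 0);
* the statistics — Cousineau–Morey within-subject error bars, balanced
  split-plot repeated-measures ANOVA

  F = MS_effect / MS_(effect × subject-within-group),

  with the (2, 36)/(1, 18) df pattern of a 10 + 10 subject, 2 × 3
  within-cell design, post-hoc paired t tests, and the per-subject
  (Task 4 − Task 2) difference analysis with its two-sample follow-up.

See `docs/methods.md` for models, parameters, and design decisions.

## Worked example

```python
from pstpupil import StudyConfig, run_study

cfg = StudyConfig(n_per_group=5, n_sets=2, set_size=10, master_seed=1)
report = run_study(cfg, with_training=False)
print(report.group_table.to_string(index=False))
```

```
time   group  task  pupil_pct_change  accuracy_pct  rt_mean_s
 pre control     2              0.00          92.0       0.97
 pre control     3             -0.29          89.0       0.99
 pre control     4              1.82          90.0       0.97
 pre trained     2              0.00          90.0       0.98
 pre trained     3             -0.36          90.0       0.97
 pre trained     4              1.90          88.0       0.93
post control     2              0.00          92.0       0.90
post control     3             -0.17          90.0       0.93
post control     4              1.62          88.0       0.88
post trained     2              0.00          88.0       0.91
post trained     3             -0.50          89.0       0.89
post trained     4             -0.56          90.0       0.89
```

Each row is a group × phase × task cell: mean pupil percent change from
Task 2 (Task 2 ≡ 0 by normalization), percent correct over the
individually counted central/peripheral responses, and mean reaction
time.  Before training both groups dilate ~2% more for Task 4 than
Task 2; after training the trained group's Task-4 response collapses to
the Task-2 level while controls are unchanged — the efficiency signature
the analysis is designed to detect.  The follow-up two-sample t on each
subject's (post − pre) change of the Task 4 − Task 2 contrast prints,
for this small run:

```
                                  contrast  mean_trained  mean_control       t  df      p
(post-pre) Task4-Task2, trained vs control       -2.4567       -0.1964 -1.6096   8 0.1461
```

(At this toy size the effect is visible but not significant; the
full-scale default design, `StudyConfig()`, detects it.)

A command-line interface wraps the same machinery:

```bash
pstpupil simulate --config cfg.json --out data/ --seed 11   # dataset on disk
pstpupil analyze  --config cfg.json --out report/           # end-to-end report
pstpupil report   --data report/                            # print the tables
```

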