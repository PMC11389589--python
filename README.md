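# vmrloc

Analysis pipeline for **hand-localization precision during early visuomotor
adaptation**, built for cycle-structured reaching experiments on a planar
manipulandum, together with a paradigm simulator so that every stage can be
exercised and validated without access to recorded data.

## The scientific problem

How precisely people can localize their unseen hand constrains implicit motor
adaptation, and this precision is usually treated as a constant of the
participant. The paradigm this package analyzes probes whether precision
instead *changes* during the first few movements of adaptation: short cycles
of 2–4 reaches under a 45° visuomotor rotation (adaptation) alternate with
cycles under veridical feedback (washout), and the final reach of every
cycle — performed without a cursor — ends with a report of the perceived hand
position, either by moving a pointer to it or by a left/right judgment of a
probe at a known angular offset (2AFC).

The pipeline's job is to turn raw 1 kHz hand paths, trial tables, and reports
into per-subject estimates of localization **bias** and **variability**
(inverse precision) by cycle type and reach number:

- **Kinematics** — movement onset (first sample with speed > 5 cm/s *and*
  radius > 0.5 cm from home), offset (speed back below 5 cm/s after the speed
  peak), direction at peak speed, extent, and the linearity index
  LI = max perpendicular deviation from the home–endpoint line / extent.
- **Screening** — reaches are rejected when too slow (> 300 ms from onset to
  the 10 cm target circle), too curved (LI > 0.2), or aimed at the wrong
  target (signed direction < −30°, two-target variant only); pointer reports
  are rejected for premature pedal presses (reported radius < half the actual
  extent) or radial errors beyond 2 SD of the subject's radial errors.
- **Pointer analysis** — angular error = angle(reported) − angle(actual),
  sign-corrected so positive always points toward the rotated cursor (CW-cycle
  errors are negated); bias is the mean, variability the interquartile range
  after subtracting each target's own bias.
- **Psychometrics** — per subject and cycle type, P("left") is fit as a
  logistic in the probe offset x (binomial GLM, logit link):
  P(left) = 1 / (1 + e^-(β₀ + β₁x)), with PSE = −β₀/β₁ (bias) and
  JND = 2·ln 3/β₁ (the 75%–25% interval; inverse precision). With two
  targets, each target's PSE is subtracted from its offsets so the curves
  align at zero before a pooled fit yields the joint JND.
- **Variability matching** — a control that equates *hand-position*
  variability between cycle types by iteratively removing extreme adaptation
  trials and close-to-median washout trials until adaptation dispersion falls
  just below washout, then recomputes localization variability on the
  survivors.
- **Simulator** — schedules for the three experiment variants (reaiming,
  aim-direct, cued localization), a single-state linear learner
  x ← A·x − B·e per target (producing aftereffects that grow with the number
  of rotated reaches), minimum-jerk trajectories with motor noise, and
  localization reports with cycle-type-dependent bias and dispersion — all
  with known ground truth for parameter-recovery testing.

## Worked example

Simulate a small reaiming experiment (4 subjects, 3 blocks) and run the full
pipeline:

```python
from vmrloc.pipeline import RunConfig, run_pipeline

run = RunConfig(experiment_id="exp1", localization_method="pointer",
                simulation=dict(n_subjects=4, config=dict(n_blocks=3,
                                                          baseline_block=False)),
                seed=42)
result = run_pipeline(run)
print(result.summary)
```

which prints (medians across subjects, degrees):

```
bias_deg          adaptation 1.79   washout 0.57
iqr_deg           adaptation 10.48  washout 5.86
aftereffect_deg   2: 14.68   3: 18.33   4: 21.31
matched_loc_iqr   adaptation 9.59   washout 5.34
```

Reading the numbers: localization reports are biased ~1.8° toward the rotated
cursor during adaptation but only ~0.6° during washout, and are markedly more
variable in adaptation (IQR 10.5° vs 5.9°) — the generator's built-in
precision loss, recovered by the pipeline. Aftereffects grow with the number
of preceding rotated reaches (implicit learning), and the adaptation–washout
variability difference survives the hand-position matching control, showing
it is not an artifact of more variable reach endpoints.

The same analyses are available from the shell:

```sh
vmrloc simulate --experiment exp1 --method pointer --subjects 4 --seed 42 --out data/
vmrloc run --data data/ --out results/
vmrloc report --results results/
```

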