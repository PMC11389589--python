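# Methods

This note documents the models, estimators, numerical conventions, and
design choices in `vmrloc`, and what the synthetic generator does and does
not emulate.

## Conventions

Angles are in degrees, 0° pointing straight ahead from the home position and
positive counter-clockwise (CCW); the unit vector at angle θ is
(−sin θ, cos θ). Positions are in cm with the home position at the origin for
analysis; time is in ms; traces are sampled at 1 kHz; sample indexing is
0-based. Signed movement directions follow the experiment's convention:
positive clockwise in the CCW-only variants (exp2, exp3), and positive in the
direction of expected adaptation in the alternating-rotation variant (exp1),
i.e. CW for CCW-rotation cycles and vice versa. Washout cycles inherit the
preceding adaptation cycle's rotation direction for all sign rules (the
`sign_dir` column), since their required movement direction equals that
cycle's.

## Paradigm structure

A block interleaves 18 adaptation and 18 washout cycles in strict
alternation. A cycle's length (2, 3, or 4 reaches **in total, including the
final no-feedback localization reach**) is drawn pseudorandomly with equal
counts of each length per type per block, giving 108 reaches and 36
localizations per block. This total-length bookkeeping reconciles the
"two to four consecutive reaches" framing with the per-block reach count and
with the fact that the first reach of a cycle never carries a localization.
Target jitter is redrawn once per cycle (uniform within the configured
bound) and shifts the hand and cursor targets together, preserving their
angular offset; the jitter-per-cycle reading was chosen because jitter is
specified "between cycles". In the alternating variant the rotation
direction reverses between consecutive adaptation cycles, CCW rotation being
paired with the lower target (20°) and CW with the upper (65°), so the
cursor target always coincides with the other displayed target; the first
direction of each block is randomized.

## Synthetic learner

The generator stands in for human participants; its purpose is to produce
raw data with the statistical structure the analysis assumes, under known
ground truth — not to model any particular participant.

Each hand target has a single implicit state x (deg, deviation from the aim
point). On every feedback reach,

    x ← A·x − B·e,      e = cursor direction − aim direction,

with retention A = 0.95 and learning rate B = 0.15 per reach by default; the
no-feedback localization reach applies retention only (x ← A·x), since no
cursor error is available. The error driving the state is the cursor's
deviation from the *aim point* (the sensory prediction error). Under
aim-direct instructions this equals the cursor error relative to the target,
so the state follows the familiar recursion x ← A·x − B·(r + x) with fixed
point x\* = −B·r/(1 − A + B). Under full instructed reaiming the
performance error is ≈ 0 by construction, and a performance-error-driven
state would never adapt; driving it by the cursor-vs-aim error instead
yields the implicit drift and the growth of aftereffects with the number of
rotated reaches that the paradigm is designed to reveal. Separate states per
target are kept in the alternating variant (otherwise the two rotation
directions would cancel through a shared state). The late-stage *adjustment*
of the aiming strategy seen in experienced participants is deliberately not
modeled; reaiming is a fixed full 45° re-aim plus Gaussian execution noise
(SD 4° by default) on adaptation reaches.

Trajectories are straight minimum-jerk paths (position profile
10u³ − 15u⁴ + 6u⁵) of 10.5 cm (stopping just behind the 10 cm target) over
400 ms, with direction = intended + N(0, 2.8°) motor noise and small extent
noise. The motor-noise SD was set so that washout hand-direction dispersion
is in the low-single-degree IQR range, and the strategy noise so that
adaptation hand positions are substantially more variable than washout, as
the matching control requires. Pathological presets (`slow`: 900 ms;
`curved`: a half-sine bow with LI = 0.3) exercise the screening rules.

Pointer reports add s·bias(cycle type) + N(0, σ(cycle type)) to the actual
endpoint angle (s = +1 for CCW cycles, −1 for CW: bias points toward the
rotated cursor) and N(0, 0.5 cm) to the radius. 2AFC responses are drawn
from a logistic in (probe offset − s·bias) with a cycle-type-dependent
slope; probe offsets (±3.33°, ±10°, ±20°) are counterbalanced within block ×
cycle type. The defaults (bias 2.0°/0.5°; σ giving angular-error IQRs
≈ 10.6°/6.0° with baseline ≈ 6.8°; slopes giving JNDs ≈ 10.4°/6.9°) are
chosen to emulate group-level magnitudes typical of the reaiming variant of
this paradigm. They are paradigm-informed generator defaults, exposed in
`SimParams`, and never asserted as ground truth. The slope parameter is a
per-cycle-type map so that precision differences between adaptation and
washout can be generated and recovered.

What the generator does **not** emulate: participant exclusions, reaction
times, online feedback corrections, submovements, sensor noise in the 1 kHz
signal, drifts of bias across the session, or the late-stage strategy
adjustment. Passing recovery tests therefore show that the pipeline's
estimators are unbiased and correctly plumbed under the assumed structure;
they do not validate the rules (e.g. the smoothing-free velocity estimate)
against the idiosyncrasies of recorded data.

## Kinematic analysis

Speed is estimated by central differences of position without smoothing —
appropriate for the noise-free simulated traces; a low-pass Butterworth hook
(`lowpass_hz`) exists for recorded data and is off by default, since
appropriate filter settings depend on the acquisition setup. Onset requires speed > 5 cm/s
*and* radius > 0.5 cm at the same sample; offset is the first drop below
5 cm/s after the first post-onset speed peak (starting at the peak avoids
triggering on sub-threshold jitter right at onset; with a double-peaked
profile the offset falls after the *first* peak). If speed never drops below
threshold the last sample is used and flagged. "Direction at maximum
velocity" uses the first global speed maximum in [onset, offset] as
tie-break, and measures the angle of the *position* relative to home at that
time (stable under noise; switchable in principle to the instantaneous
velocity vector). Extent is the radial distance of the endpoint (position at
offset). All analyses include feedback and no-feedback reaches alike.

## Screening

The three kinematic rules (too slow: > 300 ms from onset to the 10 cm
circle, or never crossing it; curved: LI strictly > 0.2; wrong target:
signed direction < −30°, two-target variant only) are evaluated
independently and all violated reasons recorded. The premature-press rule is
read as *reported radial distance < half the actual extent* — the literal
alternative (error magnitude below half the extent) would reject nearly
every good report. The 2 SD radial-outlier rule uses a single pass: the SD
is computed once per subject over all reports before any removal (stored
with the result, making re-screening idempotent), because a single threshold
is specified, not an iterative trim. Per-subject rather than pooled SDs were
chosen (the alternative is a one-line change, `radial_sd=`). With fewer than
3 reports the outlier rule is skipped with a warning.

## Localization summaries

Bias is the mean of sign-corrected angular errors (the defining operation is
"averaging"); group tables emit both mean ± SD and median ± IQR so either
reporting convention can be reproduced without a normality gate. Variability
is the IQR after subtracting each target's own bias within subject × cycle
type, so a between-target bias difference cannot inflate dispersion.
Quartiles use linear interpolation (type 7) by default; the convention is a
config knob because it materially affects the estimate at ~36 reports per
bin. Bins with < 4 reports are flagged. Reach-number binning (the
localization reach is the last of its cycle, so reach number = cycle length)
applies to exp1/exp2; exp3 is summarized by cycle type only. The pointer
performance score interpolates **linearly** between the two stated anchors
(100 points at 0 cm, 0 at ≥ 10 cm) — the simplest graded rule consistent
with both.

## Psychometric fits

Fits are maximum-likelihood binomial GLMs with a logit link, one curve per
subject × cycle type (× target), pooling blocks. PSE = −β₀/β₁ and
JND = 2·ln 3/β₁ follow from the logistic form; a test verifies they equal
the 50%/75%/25% crossings found by bisection. "Left" is modeled as CCW along
the probe arc given the workspace orientation; the coding is a documented
convention and can be flipped by relabeling responses. Complete separation
(no overlap between "left" and "right" offsets, or an unbounded slope) is
handled by refitting with a weak ridge penalty (10⁻²) on the slope and
raising `separation_flag`; a non-positive slope marks the fit degenerate
with an infinite JND. For the two-target variant, the joint precision
estimate subtracts each target's PSE from its offsets before the pooled fit,
which removes the between-target bias component from the JND; the
sign-corrected PSEs are averaged across targets for the bias summary.

## Variability matching

The matching control is defined by an objective (equate hand-position
variability) and a stopping rule ("just below", implemented as a strict
inequality); the removal granularity is genuinely open. This implementation removes
exactly one trial from each cycle type per iteration — the adaptation trial
farthest from the adaptation median, and the washout trial closest to the
washout median — recomputing medians and dispersions every iteration; ties
break toward the earlier trial index, making the procedure deterministic.
This symmetric one-per-type rule is one admissible reading; it terminates in
at most min(n) − floor iterations (floor 8 trials per type by default) and
returns a diagnostic failure result if the floor is reached first.
Hand-position variability is the IQR of target-relative signed directions,
consistent with the package's other dispersion measures (switchable to SD).
Dispersion is not strictly monotone across iterations: the interpolated
quartile grid shifts as n shrinks, so small transient increases are
possible; tests assert monotonicity up to this jitter on large fixtures.

## Problem sizes and tolerances

Parameter-recovery tests run the full pipeline at study scale (15 subjects,
6 blocks) over 20 generator seeds, which recovers the bias difference to
±0.5°, the IQR ratio to 15%, and monotone aftereffect growth in ≥ 18/20
seeds; `scripts/acceptance.py` uses one seed at the same scale. Geometric
closed forms (LI of straight/triangle/semicircle paths) are checked to
1e-9; event detection is checked for exact equality against an exhaustive
sample-scan oracle; Gaussian-dispersion closed forms (IQR = 1.349σ,
JND = 2·ln 3/slope) at n = 10⁴ and n = 2520 to 2–5%.

## Known limitations

- The smoothing-free velocity estimate is tuned to clean simulated traces;
  recorded data need the low-pass hook and possibly different thresholds.
- The learner has no trial-to-trial retention loss between cycles that do
  not use a target (states persist untouched while the other target is in
  play).
- The deposited-data adapter maps columns by configuration only; it has not
  been exercised against any specific deposit layout.
- No inferential statistics: the pipeline exports tidy per-subject tables
  (bias/IQR/PSE/JND by cycle type × reach number) for any stats package.
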