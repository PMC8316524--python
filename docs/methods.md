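# Methods

## Overview

`gaituniq` quantifies how individual a person's walking kinematics are.  The
pipeline reduces a walking trial to a fixed-length *gait vector*, pools the
vectors of a cohort, extracts principal-component features, and asks how
reliably two feature vectors can be classified as coming from the same or
from different people.  The equal error rate (EER) of that decision is then
converted into population-uniqueness probabilities.

Because no public marker-level cohort of this design exists, the package
ships a synthetic cohort generator with controlled inter-subject and
intra-subject variance; every downstream stage is exercised and tested
against it.

## Gait representation

A trial is 17 labeled anatomical points (head, left/right shoulders,
elbows, wrists, hips, knees, ankles, toes, heels) sampled at a known frame
rate, in metres.  Two auxiliary points, mid-hip and mid-shoulder, are the
arithmetic midpoints of the hip and shoulder pairs.  Sixteen segments
connect the points (trunk, neck, two clavicles, upper arms, forearms,
thighs, shanks, feet, and heel→ankle links); each segment's orientation is
the unit vector from its proximal to its distal point — its direction
cosines in the laboratory frame.

Processing steps per trial:

1. **Lab alignment.** The trial is rotated about the vertical (Z) axis so
   the mid-hip net horizontal displacement points along +X.  Trials with
   net horizontal progression below 1 µm are rejected.
2. **Heel-strike detection.**  Strikes are prominent minima of the heel's
   vertical coordinate.  Candidate minima need a prominence of at least 5%
   of the signal range; the gait period is estimated from the heel-height
   autocorrelation; and the final event set is the chain of candidates that
   maximises total minimum depth under the constraint that consecutive
   events are 0.65–1.45 periods apart (a small dynamic programme).  The
   chain constraint resolves split or secondary minima that plain
   prominence/spacing thinning mis-handles.  Endpoint frames count as
   events when they reach the depth of the interior minima (within 5% of
   the range).  K events delimit K−1 cycles.
3. **Cycle cutting and resampling.**  Each cycle spans heel strike to next
   heel strike (half-open for cycle membership; the closing strike frame is
   included as interpolation endpoint).  The 48 orientation channels are
   linearly interpolated onto 101 equally spaced points of normalised time
   [0, 1], and each interpolated cosine triple is re-normalised to unit
   length (linear interpolation leaves the unit sphere; the invariant is
   unit norm to 1e−9).
4. **Flattening.**  The 101 × 16 × 3 block becomes a 4848-component gait
   vector, segment-major, then axis (x, y, z), then frame.  The flattening
   is exactly invertible.

Spatiotemporal parameters per cycle: walking velocity = mid-hip horizontal
displacement / cycle duration; cadence = 2 steps per cycle in steps/min;
step length = velocity × half the cycle duration.

Conventions that the representation fixes but that have no single
"correct" choice: the exact 16-segment connectivity (any spanning set of
16 edges over the 19 points is admissible; ours is the canonical list in
`gaituniq.anatomy`, configurable via `SegmentSet`), the proximal→distal
direction of each segment (trunk points mid-hip→mid-shoulder, heel links
heel→ankle), and the segment-major flattening order.

## PCA features and variance accounting

The pooled gait vectors are mean-centered and decomposed by PCA (full
SVD).  Score variances use the N−1 denominator.  Components are retained
while their variance exceeds 1e−12 of the leading variance; on generic
data this reproduces the rank N−1 of N mean-centered vectors while
discarding numerical noise.  A numerically zero leading variance (all
vectors identical) yields rank 0.

For each component:

* **explained variance** — the score variance over the whole pool;
* **intra-subject variance** — the sample variance (denominator n−1,
  unbiased at the design's n = 4 cycles/subject) of each subject's scores,
  averaged with equal weight per subject;
* **variance ratio** — intra-subject / explained variance.  Both numerator
  and denominator are raw score variances, so the ratio is scale-free.
  Components with zero explained variance are flagged, not divided.

A low ratio marks a feature that differs between people but is
reproducible within a person.  `reorder_components_by_ratio` sorts
components by ascending ratio (stable; ties keep the variance order;
0-based indices).  Component–parameter associations are Pearson
correlations; zero-variance columns give NaN entries.

## Verification

Feature vectors are the first k PCA scores (k = 30 by default).  Cases are
unordered pairs: all within-subject pairs (Σ C(n_s, 2); 2928 at the
488-subject design) and an equal-sized uniform subsample, without
replacement and with a logged seed, of the C(S, 2)·t² cross-subject pairs
(1,901,248 at that design), 5856 cases in total.

The pair feature is the signed difference f₁ − f₂.  The L1/L2 rules and
the linear/polynomial margin classifiers consume the elementwise absolute
difference |f₁ − f₂| (the natural symmetric reduction, consistent with the
distance formulas); the RBF margin classifier consumes the signed
difference and is trained with sign symmetrisation — every training case
is augmented by its negation — because pair order is arbitrary.
Symmetrisation is toggleable.

Margin classifiers are SVMs with C = 1, polynomial degree 3 with coef0 = 1
(the inhomogeneous cubic kernel; the homogeneous one degenerates at the
origin where same-pairs concentrate), RBF width gamma = 1/(k · feature
variance), and solver tolerance 1e−5 so the decision function is
reproducibly symmetric under pair reversal.  No hyperparameters are tuned.
The L1/L2 rules accept "same" iff distance ≤ threshold; the threshold is
chosen on the training folds by maximising accuracy, ties broken toward
the smaller threshold.

Evaluation is stratified fivefold cross-validation (stratified by the
same/different label at the pair level, which permits subject overlap
across folds — the fidelity-first choice; a subject-disjoint split is a
straightforward extension).  Accuracy is the pooled out-of-fold correct
proportion, and the ROC is computed on pooled out-of-fold scores.  The
acceptance-threshold sweep visits every observed score; FAR is the
proportion of different-person pairs accepted, FRR the proportion of
same-person pairs rejected; the EER is read where FAR = FRR, linearly
interpolated between the adjacent thresholds where FAR − FRR changes sign.
The implementation is verified against an exhaustive brute-force sweep to
1e−9.

**Uniqueness arithmetic.**  For EER e and population size P (requiring
e·P ≤ 1): the probability of misattributing one probe sample is at most
e·P (union bound); special uniqueness is 1 − e·P; general uniqueness —
every member of the population unique — is (1 − e·P)^P.

## Synthetic cohort

The marker-level generator emulates the acquisition design: 488 subjects,
2 trials × 2 cycles each, 120 frames/s, cycle duration 1.03 s on average.
Each segment's orientation curve over the cycle phase is a truncated
Fourier series (3 harmonics) per axis, normalised to the unit sphere per
frame.  A fixed built-in population mean gait (documented constants in
`gaituniq.simulate`) defines the template; a subject is a Gaussian draw of
all 336 Fourier coefficients around it with spread σ_b
(`inter_subject_sd`), and every cycle re-perturbs the coefficients with
spread σ_w (`intra_subject_sd`).  Orientations are integrated along the
body tree from a mid-hip root that advances at the subject's walking
speed, with physiological vertical bob (lowest at double support) and
lateral sway.  The left side is the right side phase-shifted by half a
cycle and mirrored in Y.  The leg templates are engineered so the heel
height has exactly one clear minimum per cycle (the shank's horizontal
excursion vanishes only at the strike), so event detection is genuinely
exercised.  Trials walk in a random heading, exercising lab alignment.

Defaults (chosen once as plausible for comfortable adult walking; the
timing constants follow the emulated design):

| parameter | default | units | role |
|---|---|---|---|
| `frame_rate` | 120 | frames/s | capture rate |
| `cycle_duration_mean` | 1.03 | s | population mean cycle |
| `cycle_duration_sd` | 0.06 | s | between-subject duration spread |
| `cycle_jitter_sd` | 0.015 | s | cycle-to-cycle duration jitter (lognormal, strictly positive durations) |
| `inter_subject_sd` (σ_b) | 0.06 | – | coefficient spread between subjects |
| `intra_subject_sd` (σ_w) | 0.015 | – | coefficient spread between cycles |
| `walking_speed_mean` | 1.25 | m/s | population mean speed |
| `walking_speed_sd` | 0.15 | m/s | between-subject speed spread |

Subject stature scales all segment lengths by N(1, 0.04), clipped to
[0.85, 1.15].  Spatiotemporal parameters derive from the generated speed
and duration, so the correlation stage has known ground truth.

The feature-level generator (`generate_feature_cohort`) bypasses the
marker stage: subject means drawn with per-component SD σ_b, observations
around them with SD σ_w.  Its variance decomposition is exact, so the
realised intra/explained ratio converges to σ_w²/(σ_w² + σ_b²) — the
closed form the parameter-recovery tests check.

**What the generator does not emulate:** biomechanically validated joint
dynamics or ground-reaction forces, soft-tissue/marker noise, demographic
structure, gait pathology, and long-term (inter-visit) variability.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and well-calibrated under a controlled variance model — not that
any particular real-world accuracy or EER is attainable.  Verification
numbers on the synthetic cohort (e.g. RBF accuracy ≈ 0.995, EER ≈ 0.005
at the defaults) characterise the simulation, not human gait.

An additional, deliberate source of intra-subject variability: detected
strike frames quantise to the frame grid and the strike basin is flat, so
cycle boundaries wander by a few percent of the cycle between cycles.
With σ_w = 0 *and* frame-aligned cycles (integer frames per cycle, no
duration jitter) the four vectors of a subject are identical to ~1e−9;
with the default non-integer 1.03 s cycle they differ at the 1e−2 level
from boundary quantisation alone, which is realistic but means "σ_w = 0 ⇒
bit-identical vectors" holds only on the aligned grid.  The degenerate
control tests use that grid.

## Problem sizes and runtime

The test suite and the acceptance script run the full 488-subject design
(1952 × 4848 PCA, ~15 s) where the quantity under test depends on it, and
scaled-down cohorts (6–60 subjects, or feature-level cohorts of 2000
observations) for statistical properties whose expectations are
size-independent.  These sizes are the package's own choices and are
stated in the relevant tests and scripts.

## Known limitations

* The 16-segment connectivity and segment direction conventions are one
  admissible choice; a different spanning set would change the gait-vector
  coordinates (not the machinery).
* Pair-level fold stratification permits the same subject to appear in
  training and test folds (as the balanced-pair design implies); the EER
  should be read as within-dataset separability, not out-of-population
  generalisation.
* The uniqueness arithmetic treats the EER as a per-comparison error
  probability and uses a union bound; it is an approximation, loose for
  large populations.
* Heel-strike detection assumes a quasi-periodic heel-height signal with
  at least ~1.5 cycles of data.
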