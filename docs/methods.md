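# Methods

`pdgait` implements a complete vertical ground reaction force (VGRF) gait
pipeline for Parkinson's disease (PD): record parsing, signal conditioning,
gait-cycle segmentation and contact-event detection, spatiotemporal /
asymmetry / fluctuation-magnitude / double-support feature extraction,
SMOTE class balancing, and two shallow neural classifiers — a binary
PD-vs-control screen and a three-class Hoehn & Yahr (H&Y) 2 / 2.5 / 3
staging model.  This note records the model, the tunables that matter, the
numerical choices, what the synthetic cohort does and does not emulate, and
the design calls made where the protocol left the choice open.

## Input data model

A walking record is plain whitespace-delimited text, one row per 10 ms
sample, 19 columns: elapsed time (s), eight left-foot and eight right-foot
insole force sensors (N), and the two per-foot sensor sums.  On load,
negative readings are clamped to zero (force sensors cannot pull; the count
is logged), the time base must be uniform at 100 Hz within 1 µs, each total
must match its sensor sum within 1% of the total's maximum (source-rounding
tolerance), and records shorter than 2 s are rejected because at least one
full gait cycle is needed downstream.  Sensor 1 is taken as the heel sensor
and sensor 8 as the toe/forefoot sensor; both are configurable.

## Signal conditioning

All 18 traces pass through a running median (default window 3 samples =
30 ms, edge replication).  The window is deliberately short: it removes
single-sample sensor spikes without smearing the heel-strike transient; no
low-pass filter is applied.  Per-foot aggregate force is the elementwise
sum of the eight sensors (the recorded total column is an alternative
source; the two agree within the load-time consistency contract).
Aggregates are normalized by body weight (force / (mass x 9.81 m/s²)), the
field standard, so a value of 1 means one body weight; unit-peak
normalization is the automatic fallback when body mass is unknown.

## Gait cycles and contact events

Stance onset/offset is detected by threshold crossings of the aggregate
force, with the threshold defaulting to 5% of the record's aggregate
maximum (absolute Newtons are configurable).  Leading/trailing partial
cycles are discarded, as is any cycle with a stance or swing phase of
50 ms or less.  Timestamps are reported at sample resolution (10 ms); no
sub-sample interpolation is attempted because all downstream quantities are
differences of many such timestamps.

Initial contact (IC) and terminal contact (TC) are located with a peak
detector: IC is the first prominent local maximum of the heel sensor in the
first 40% of stance, TC the last prominent maximum of the toe sensor in the
last 40%; prominence must exceed 10% of that sensor's record maximum.  The
40% windows keep the heel-strike and push-off peaks of a double-hump
profile from being confused; both windows and the prominence are
configurable.  A cycle with no qualifying peak carries a missing event and
is dropped by validation.

### Cycle validation

For each left-referenced cycle the four events must occur in the
physically realizable order

    IC_R < TC_L < IC_L(next) < TC_R,  with the previous TC_R before IC_R,

i.e. contralateral heel strike, ipsilateral toe-off, the ipsilateral heel
strike that closes the cycle, contralateral toe-off.  An alternative
literal inequality (`IC_L < TC_R(prev) < IC_R < TC_L`) is retained as a
validation-mode option; with the natural per-cycle indexing it is also
satisfied by healthy alternating gait, so both modes accept the simulator's
cohorts.  Cycles failing the configured rule, or missing any event, are
excluded and counted.

## Features

**Spatiotemporal (per cycle).**  Stride time GCT = t_start(i+1) −
t_start(i); stance = t_end − t_start; swing = GCT − stance.  Ratios default
to the convention in which stance ratio = stance/GCT and swing ratio =
swing/GCT (they sum to 1); the alternative printed convention
(swing ratio = GCT/stance) is selectable as `PAPER_LITERAL`.  Stride
length = GCT x walking speed when a speed is on file (the records carry no
positional data).

**Asymmetry index.**  Mean over paired cycles of |L(i) − R(i)| / L(i),
computed on stride times by default (stance times by option).  It is zero
iff the two series are identical and invariant to common scaling.

**Fluctuation magnitude variability (FMV).**  Per sensor pair i,
FMV_i = |L_i − R_i| / L_i x 100, where L_i and R_i are the sensor's mean
forces over its own loaded samples (> 1 N floor).  Means are compared —
not instantaneous samples — because the feet alternate: at any instant one
foot's sensor is unloaded, so a sample-wise ratio saturates near 100% for
every sensor and carries no ranking information.  The 1 N floor excludes
swing-phase noise from the load means.  The two top-ranked sensors (ties to
the lower index) feed the classifier; on the reference cohort's printed
FMV row the ranking selects sensors 3 and 7.

**Diagnosis vector (34 features per record).**  Four primary elements
(record means of the normalized aggregate left/right VGRF and the two
selected sensors' FMV); left/right stance, stride and swing times; stance,
swing and swing/stance ratios (record means over validated cycles);
left/right maximum IC and TC forces; coefficient of variation
(std/mean x 100), mean, and standard deviation of each primary element
computed across per-cycle values; average step distance
(speed x GCT/2 — GCT/2 approximates step time); and the stride asymmetry
index.  A record lacking walking speed cannot produce a step distance and
is flagged incomplete (excluded from training); a record lacking body mass
falls back to unit-peak normalization and is only flagged as imputed.

**Severity features.**  Per validated cycle j, with GCT_L the left stride
time: initial double support IDS = (TC_R(prev) − IC_L)/GCT_L x 100 (left
heel strike to the right toe-off just after it), terminal double support
TDS = (TC_L − IC_R)/GCT_L x 100 (right heel strike to left toe-off),
DS = IDS + TDS and Limp = |IDS − TDS|.  The equations are stated here with
the contact labels that make both spans positive double-support intervals;
the first cycle of a record lacks the preceding contralateral toe-off and
is skipped.  Because IC and TC are force *peaks*, these spans run
heel-strike-peak to push-off-peak and slightly undershoot onset-based
double support; the simulator's truth events use the same convention, so
recovery is tested like-for-like.  The staging classifier receives the
record means and standard deviations of IDS/TDS/DS/Limp plus per-foot
spatiotemporal means (18 features).

## Class balancing

SMOTE: for each requested synthetic sample of a class, a real member is
drawn (cycling through a seeded permutation), one of its k = 5 nearest
real same-class neighbours (Euclidean distance on a min-max-scaled copy so
no feature dominates) is chosen, and the new point is the convex
combination x + u(x_n − x), u ~ U[0,1], interpolated in original units.
Real rows are never modified.  The default amounts (+20 at H&Y 3, +28 at
2.5, +0 at 2) turn the 10/28/55 staging cohort into 30/56/55.  During
cross-validation SMOTE is applied inside training folds only — synthetic
points never reach a test set, avoiding optimistic leakage; a global
(pre-split) mode exists for reproducing workflows that balanced first.

## Classifiers

Both networks are single-hidden-layer perceptrons with tanh hidden units
and softmax outputs, trained full-batch to minimize the MSE between softmax
outputs and one-hot targets (cross-entropy is available as an option, the
MSE default mirrors the reported toolbox performance numbers).  Inputs are
scaled per feature to [−1, 1] from the training minima/maxima (constant
features map to 0 with a warning; unseen data is not clipped).  Weights are
initialized uniformly at ±1/sqrt(fan-in) from the seeded generator; every
operation is a pure function of (data, seed).

Training algorithms: **Rprop** (iRprop−; η+ = 1.2, η− = 0.5, Δ0 = 0.07,
Δmax = 50), **Levenberg-Marquardt** (damped Gauss-Newton on the residual
Jacobian; with at most ~1000 weights the normal-equations solve is cheap;
damping x10 on rejection, x0.1 on acceptance), **gradient descent with
momentum** (0.9, learning rate 0.05), and **Møller's scaled conjugate
gradient**.  Early stopping holds out 15% of the training rows
(stratified), stops after 6 consecutive validation-MSE increases
(patience), and restores the best-validation weights; maximum 1000 epochs.
The diagnosis network defaults to 25 hidden Rprop units, the staging
network to 13 hidden Levenberg-Marquardt units — the architectures the
protocol selected from its (algorithm x hidden units) grid, which
`architecture_search` re-runs on request (scored by hold-out validation
MSE, ties to fewer hidden units).

Evaluation: confusion matrices use rows = predicted, columns = target.
The binary panel reports ACC, ERR = 1 − ACC, SN, SP, PREC and
FPR = 1 − SP; ratios with zero denominators are reported absent, never
as 0.  Cross-validation schemes: a single stratified 70/15/15 hold-out
("1-fold"), stratified k-fold (stratification keeps the 10-member H&Y-3
class represented in every fold), and leave-one-out; fold test sets
partition the data exactly once and the pooled confusion matrix aggregates
all test predictions.

## Synthetic cohort

The simulator emits ground-truthed records in the same text dialect.  Each
stance is a fixed waveform template over normalized stance phase: the
total force is a raised-cosine composition that morphs from the healthy
double hump (weight-acceptance and push-off peaks near 18% and 82% of
stance, mid-stance valley at ~45% of peak) to a single broad central peak
as the `flatten` parameter goes 0 → 1, windowed to exact zero outside
stance so threshold segmentation is unambiguous at zero noise.  The total
is split across the eight sensors by smooth share functions; the heel and
toe shares are steep exponential gates so the heel-sensor peak falls just
after ground contact and the toe-sensor peak just before lift-off,
preserving the validation event order by construction.  Per-sensor truth
events (stance bounds, IC/TC peak times and magnitudes) are recorded from
the noise-free traces.

Stride durations are i.i.d. with mean base_gct x (1 + severity x
(pd_gct_factor − 1)) — severity 1 lengthens the stride by the full 40%
factor — and a configurable CV; the right foot interleaves at 50% phase,
perturbed alternately by the `asymmetry` parameter (which also shortens the
right stance slightly), producing per-cycle stride asymmetry without
long-run drift.  Gaussian sensor noise (default 2 N in cohorts) is added
and clamped at zero.

Cohorts map H&Y stage to a mean severity (2 → 0.32, 2.5 → 0.62, 3 → 0.80)
with a within-stage SD of 0.10, so neighbouring stages overlap moderately —
as in clinical staging — and the top stage sits closer to 2.5 than 2.5 does
to 2, reflecting saturating late-stage gait change; this makes the
under-represented stage-3 class genuinely hard before rebalancing.
Severity drives stride time, stride-time CV, stance fraction (hence double
support, stage-monotone), timing asymmetry, waveform flattening, and a
per-sensor left/right loading imbalance whose scale is largest on sensors
3 and 7; walking speed decreases with severity.  Default cohort records
are 25 strides (~30 s of walking, shorter than the ~2 min reference
recordings; the test-suite problem sizes were chosen so the full suite and
the acceptance run stay lightweight).

**What passing tests do and do not show.**  The simulator is
phenomenological: raised-cosine templates with stage-monotone parameters,
not a biomechanical model.  Real records add turns, freezing-of-gait
episodes, drift, inter-subject waveform idiosyncrasy and label noise, none
of which are emulated.  Classifier accuracies on simulated cohorts
therefore validate the pipeline's mechanics (feature recovery, balancing,
training, evaluation) under known effect sizes — they are not evidence
about clinical performance.  The published headline accuracies can only be
compared against the real public accession via the `reproduce` subcommand,
which prints them side-by-side without asserting equality.

## Numerical choices and degenerate inputs

- Thresholds/tolerances: 1e-6 s time-step uniformity; 1% total-vs-sum
  consistency; 50 ms minimum phase; 1 N FMV floor; 10% peak prominence.
- Ties: sensor ranking breaks toward the lower index; prediction argmax
  toward the lower class index.
- Degenerate inputs: all-zero traces segment to an explicit "fewer than 2
  cycles" error; an all-zero trace under unit-peak normalization returns
  zeros; empty feature-table writes produce a header-only file; a
  single-member class rejects oversampling; k-neighbours is clamped to
  class size − 1 with a warning.
- Determinism: one top-level seed flows to cohort simulation, fold
  splitting, SMOTE and weight initialization; per-fold seeds are derived
  offsets.  Reports are byte-identical across reruns with the same seed.

## Known limitations

- Only the 100 Hz, 19-column text dialect is read; other rates are
  rejected rather than resampled, and WFDB binary containers are out of
  scope.
- Event times are peak-based at sample resolution; double-support measures
  undershoot onset-based definitions by roughly the heel-peak lag plus
  push-off lead (~0.05–0.1 s per boundary).
- The Levenberg-Marquardt implementation materializes the full residual
  Jacobian; it is intended for networks up to a few thousand weights.
- One feature vector per record; per-subject aggregation (the default unit
  of analysis for staging) is a mean over that subject's records.
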