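# Methods

## Scope and model

`remsleep` analyses visually scored polysomnography nights (30-second
epochs, stage vocabulary W, S1–S4, REM, UNSCORED) together with
eye-movement data from the electrooculogram (EOG), for cohorts shaped
like a two-group clinical sleep study: a patient group (here labelled
TRD, treatment-resistant depression) recorded at baseline and after a
single ketamine infusion, and healthy volunteers (HV) recorded at
baseline.  The quantities of interest are the classical REM-sleep
depression markers:

* **REM latency (RL)** — elapsed minutes from sleep onset (first stage-2
  epoch) to the first REM period, wake included;
* **Total Night RD** — eye movements across the night's REM sleep per
  minute of REM time (counts/min);
* **RD1** — the same density restricted to the first REM period, the
  candidate endophenotype and treatment-response predictor;

plus the supporting architecture panel: TST, SWS, WASO, REM Time, REM
Percent, REM Efficiency and SE.

## Definitions and conventions

The epoch grid is 0-based with half-open intervals; every duration is
`epochs × 0.5` minutes.  Sleep onset is the first S2 epoch.  "Final
waking" is one past the last sleep epoch, so terminal wake is excluded
from WASO and all window metrics are invariant to appending wake at the
end of the record.  UNSCORED epochs count as neither sleep nor wake and
never define a window boundary.

A **REM period (REMP)** must contain at least 3 cumulative minutes of
REM, and distinct REMPs are separated by at least 15 minutes of non-REM.
Segmentation is greedy left-to-right: REM epochs separated by less than
15 qualifying minutes belong to one candidate, and candidates under the
3-minute minimum are discarded.  The 3-minute rule applies to cumulative
REM within the candidate (not the longest run), because candidates may
contain brief non-REM interruptions by construction of the 15-minute
rule.  Whether wake epochs accumulate toward the 15-minute separation is
a config flag (`gap_counts_wake`, default true — the conservative
elapsed-time reading).  A REMP is *completed* when at least 15 minutes
of qualifying non-REM follow it before final waking; a period truncated
by the end of the night is not completed, and REM Efficiency is defined
over completed periods only.

RD1 is implemented as (eye movements within the first REMP's REM
epochs) / (REM minutes of that REMP), which carries the unit counts/min;
a doubly normalized reading (a per-minute rate divided again by minutes)
would carry counts/min² and is inconsistent with how the quantity is
tabulated in the clinical literature.  Both density numerators count
only movements falling in REM epochs (`numerator_rem_only`, default
true): the denominators are REM time, so counting NREM-epoch movements
would mix units.

SE has no single standard operationalization; the package uses
100 × total sleep minutes / lights-out-to-lights-on minutes, recorded in
config so it can be swapped.

## Eye-movement detection

Rapid eye movements are detected by amplitude alone, with no duration
criterion.  The EOG trace is band-limited to 0.3–10 Hz (4th-order
zero-phase Butterworth; a `band_hz=None` escape hatch accepts
pre-filtered data), local extrema are located at sign changes of the
first difference, and each excursion between consecutive extrema whose
peak-to-trough amplitude strictly exceeds the threshold (default 25 µV;
exactly 25 µV is not an event) becomes a candidate.  Candidates on one
channel within a refractory interval (default 0.1 s) are reduced to the
largest, which makes the detector threshold-monotone: raising the
threshold can never increase the event count.  Because one saccade
appears on both EOG channels, LOC/ROC events within a coincidence
window (default 0.2 s) are merged before epoch binning, keeping the
larger deflection; anti-phase polarity is not required by default.
Band edges, refractory, coincidence window and threshold are all
config-surfaced, as none of them is standardized in the clinical
definition of the metric.

## Statistics

Shapiro-Wilk normality results are reported per metric and group but are
advisory: the comparison workflow is always non-parametric.  Group
contrasts use the two-tailed Mann-Whitney U test and within-subject
treatment contrasts the Wilcoxon signed-rank test, with exact null
distributions when the sample permits (Mann-Whitney: both groups ≤ 20
and no ties; Wilcoxon: ≤ 25 non-zero differences with distinct
magnitudes) and the normal approximation with continuity and tie
corrections otherwise.  Zero differences are dropped before ranking.
The z statistic is always computed from the approximation formula for
reporting, alongside the p-value of the chosen method.  Each results
table forms one Bonferroni-Holm family: {RL, RD1, Total Night RD} for
the baseline group contrast and the eight additional sleep variables for
the treatment contrast; α = 0.05 throughout, configurable.  Summary
tables report mean ± SEM (SD/√n) per cell.

## Response prediction

Antidepressant response is a ≥ 50% reduction (inclusive) in HAM-D score
one day after infusion; subjects missing the day-1 score are excluded.
The harness evaluates baseline RD1 as a single predictor with a
soft-margin SVM (RBF kernel, C = 1, kernel width by the data-scaled
1/(d·var) rule — defaults of the algorithm family; with one feature the
decision boundary is near a threshold regardless) over repeated
stratified hold-out validation: default 1000 iterations of a 70–30
split, class proportions preserved within one subject in every split.
Standardization statistics are computed on each training split only.
Per iteration the harness records accuracy, TPR and FPR (reported on a
0–100 scale); test-split decision scores are standardized within the
iteration (a monotone transform, so per-iteration ROC is unchanged) and
pooled across iterations into one ROC curve, because raw SVM decision
values carry fit-specific scale and offset and pooling incommensurable
scores attenuates the pooled AUC.  The per-iteration AUC distribution
is reported alongside.  AUC is the trapezoidal area and equals the
normalized Mann-Whitney statistic with midrank ties.  The accuracy
summary is the median with a 2.5/97.5-percentile interval.  Everything
is driven by one integer seed and is bit-reproducible.

## Synthetic cohorts

No clinical recordings ship with the package; the generator produces
cohorts with the statistical structure the analysis assumes.

**Hypnograms** come from a semi-Markov episode model rather than
epoch-wise Markov transitions, so latency and episode durations are
directly controllable.  A night (default 480 minutes in bed, lights out
23:00) is: truncated-normal sleep latency (15 ± 8 min) ending in one S1
epoch and the anchored S2 onset; a first NREM segment whose duration
*is* the drawn REM latency; then up to four REM episodes with normal
durations around (14, 20, 26, 30) min (SD 3, floor 4) separated by NREM
gaps of 50 ± 8 min floored at 16 min (so segmentation recovers distinct
REMPs); NREM fill; and a terminal wake tail (10 ± 5 min).  Wake
intrudes into NREM epochs with probability 0.10 (WASO ≈ 35 min), brief
S2 interruptions hit interior REM epochs with probability 0.05 (REM
Efficiency ≈ 95%), and S3/S4 epochs replace early NREM up to a 25 ± 12
min SWS budget, front-loaded into the first two cycles.

**REM latency models** are lognormal: TRD mean 60 min (σ_log 0.35), HV
mean 90 min (σ_log 0.30), floored at 20 min.  These separations are
wider than typical clinical group means: the generator's purpose is
that the designed qualitative pattern (shorter latency and higher RD1
in patients, flat Total Night RD) is reliably recoverable at the study
sample sizes (63/41), and latency SDs implied by published SEM values
(≈ 36–45 min) would leave a latency contrast at those sizes badly
underpowered.  The defaults are therefore a design choice of the
generator, not an estimate of any study's effect size.

**Eye movements** are homogeneous Poisson within each REM epoch.  A
subject-level night-average rate λ is lognormal with mean 1.2
counts/min (CV 0.5) — *equal across groups by design*, so Total Night
RD carries no group effect.  The first REMP runs at λ × m₁ with
m₁ = 4/3 for TRD and 2/3 for HV (expected RD1 1.6 and 0.8 counts/min);
all later REM epochs run at the compensating rate (1 − f·m₁)/(1 − f)
(f = first-period share of REM time), preserving each subject's
night-average density exactly in expectation.  Post-ketamine TRD nights
multiply m₁ by 0.75 (RD1 falls ≈ 25%) with the same compensation (Total
Night RD unaffected) and scale REM episode durations by 1.15 (REM Time
≈ 90 → 103 min).

**EOG rendering** implants one single-cycle sine deflection (0.35 s,
peak-to-trough equal to the drawn amplitude) per event on both
channels, anti-phase between left and right, plus white Gaussian noise;
the input event list is the ground truth for detector evaluation.

**Clinical scores**: baseline HAM-D is normal 21.45 ± 3.98 truncated at
≥ 17 and rounded; a configurable number of subjects (default 2 of 63)
lack the day-1 score; the responder indicator is Bernoulli with a
logistic link on baseline RD1 (slope 1.5 logit per counts/min), the
intercept solved so the expected responder count among labeled subjects
equals the target (default 20 of 61); day-1 scores are then drawn
consistent with the indicator under the inclusive 50% rule (responders:
uniform 50–85% reduction, floor-rounded; non-responders: uniform 0–45%,
ceil-rounded).  Slope 0 gives the null configuration in which response
is independent of RD1.

### What the generator does not emulate

Stage microstructure (no S1 beyond the onset ramp, no REM rebound or
circadian modulation), realistic EEG/EOG morphology beyond the biphasic
deflection, demographic covariates, and any subject-level correlation
between latency, density and HAM-D beyond the RD1→response link.
Passing tests on these cohorts show that the *pipeline* measures what
the generative model encodes; they are not evidence about clinical
recordings.

## Problem sizes and numerical choices

The test suite runs the calibration checks at the study's sample sizes:
type-I error of both tests at n = 63/41 and n = 61 over 1000 null
replicates (acceptance band 0.035–0.065); segmentation against brute
force exhaustively over all 16,384 two-stage strings up to length 14;
metric recounts on 200 simulated nights (tolerance 1e-9); rate recovery
over 500 nights (3 Monte-Carlo SE); harness calibration against the
closed-form binormal AUC Φ(δ/√2) at δ = 0.87 (tolerance 0.03, 100
iterations at n = 2000) and against permuted labels (mean pooled AUC
over 10 permutations × 1000 iterations within 0.5 ± 0.05); and effect
recovery over 100 replicate default cohorts (joint Holm-significant
RD1 + RL with retained Total Night RD required in ≥ 90).  Ratios are
left unrounded; undefined metrics are explicit `None` markers, never
zeros; ties in ROC scores are handled by midranks so the trapezoidal
and rank formulations agree to machine precision.

## Known limitations

* The detector's amplitude criterion is evaluated on the band-limited
  signal, so extremely slow or very fast deflections are attenuated
  before thresholding; the band is configurable but a single default
  cannot cover every montage.
* Pooled-ROC AUC and the per-iteration AUC distribution answer slightly
  different questions; both are reported, and on small cohorts the
  pooled value inherits the sampling noise of the subjects themselves
  (SD ≈ 0.08 at n = 61), which dominates any choice of aggregation.
* With heavy class imbalance the SVM's default decision threshold is
  conservative about the minority class, so accuracy/TPR/FPR describe
  that operating point rather than an optimized one; the ROC is
  threshold-free.
* EDF/EDF+ ingestion is not implemented; the CSV dialects documented in
  the README are the supported formats.
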