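# remsleep

Analysis of REM-sleep biomarkers from scored polysomnography, for
clinical sleep research on depression and rapid-acting antidepressants.
The package computes the classical REM markers from hypnograms and
electrooculogram (EOG) eye-movement data, compares them across groups
and treatment nights non-parametrically, and evaluates the
first-REM-period density as a predictor of antidepressant response to
ketamine.

## What it computes

For a night scored in 30-s epochs (stages W, S1–S4, REM):

* **RL** (REM latency): minutes from sleep onset (first S2 epoch) to the
  first REM period, wake included.
* **Total Night RD**: eye movements across the night's REM sleep per
  minute of REM time (counts/min).  Rapid eye movements are detected
  from the EOG as band-limited deflections whose peak-to-trough
  amplitude strictly exceeds 25 µV, with no duration criterion;
  left/right-channel detections of one saccade are counted once.
* **RD1**: the same density restricted to the first REM period — a REM
  period holds ≥ 3 cumulative REM minutes and is separated from its
  neighbours by ≥ 15 min of non-REM.
* The supporting panel: TST, SWS, WASO, REM Time, REM Percent,
  REM Efficiency (over completed REM periods), SE.

Group contrasts use two-tailed Mann-Whitney U tests, treatment
contrasts the Wilcoxon signed-rank test, with Bonferroni-Holm
correction per table family and mean ± SEM summaries.  Response to
ketamine (≥ 50% HAM-D reduction at day 1) is predicted from baseline
RD1 with an RBF-kernel SVM over 1000 iterations of stratified 70–30
hold-out validation, reporting per-iteration accuracy/TPR/FPR, a pooled
ROC with its AUC, and the median accuracy with a 95% percentile
interval.

A synthetic-cohort generator (semi-Markov hypnograms, Poisson
eye-movement trains, rendered EOG, HAM-D trajectories with a
logistic RD1→response link) makes every stage testable end to end; see
`docs/methods.md` for the model and its calibration.

## Worked example

```python
import numpy as np
from remsleep import (CohortSpec, PredictionConfig, compare_groups,
                      compare_paired, holdout_validate, simulate_cohort)

cohort = simulate_cohort(CohortSpec(seed=1))      # 63 TRD + 41 HV
base = cohort[cohort.night == "baseline"]
for g in ("TRD", "HV"):
    sel = base[base.group == g]
    print(g, round(sel.rd1.mean(), 2), round(sel.rl_minutes.mean(), 1))

print(compare_groups(cohort, "rd1").p)            # baseline group contrast
print(round(compare_paired(cohort, "rd1").z, 2))  # ketamine effect on RD1

lab = base[(base.group == "TRD") & base.responder.notna()]
rep = holdout_validate(lab.rd1.to_numpy(float),
                       lab.responder.astype(bool).to_numpy().astype(int),
                       PredictionConfig(n_iterations=1000, seed=1))
print(round(rep.auc, 2), round(rep.median_accuracy, 2))
```

prints

```
TRD 1.69 65.2
HV 0.8 86.5
1.504965734959431e-07
5.69
0.7 0.68
```

i.e. the patient group shows the designed pattern — higher first-period
REM density (1.69 vs 0.80 counts/min) and shorter REM latency (65 vs
87 min), a highly significant baseline RD1 difference, a ketamine-
induced RD1 reduction (Wilcoxon Z = 5.69), and moderate predictive
value of baseline RD1 for treatment response (pooled AUC 0.70, median
hold-out accuracy 0.68).

The same pipeline runs from the shell:

```bash
remsleep simulate --seed 1 --out cohort/       # hypnogram/event/clinical CSVs
remsleep metrics --hypnograms cohort/hypnograms --events cohort/events --out metrics.csv
remsleep run-all --seed 1 --out results/       # all three analyses + manifest
```

File formats are plain CSV: hypnograms as `epoch,stage` rows with
`#lights_out=`/`#lights_on=` header comments (AASM tokens N1/N2/N3/R
are mapped automatically), events as `time_s,amplitude_uv,channel`,
clinical tables as `subject_id,group,hamd_baseline,hamd_day1`.

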