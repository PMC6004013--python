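# uromet

Analysis pipeline for urinary LC-MS metabolomics surveillance of
non-muscle-invasive bladder cancer (NMIBC) recurrence.

NMIBC is resected transurethrally (TURBT) and then monitored for years by
cystoscopy, an invasive and costly procedure. A urine metabolic profile
that shifts between the pre-resection state (**BC**) and the
post-resection state (**CTRL**) offers a non-invasive readout: during
surveillance, a drift of a patient's profile back toward the BC side can
flag recurrence. `uromet` implements the full data-analysis chain such a
study needs, from raw peak table to per-patient surveillance trajectories,
for anyone working with pooled-QC-anchored untargeted LC-MS designs.

## What it does

1. **Peak-table I/O and validation** (`uromet.core_io`) — intensity
   matrices with sample metadata (batch, injection order, role, class,
   patient, visit) in plain CSV/TSV; missing values stay distinct from
   zero; patient-wise train/validation splitting.
2. **QC-anchored batch correction** (`uromet.batch_correction`) — per
   feature and batch, a support-vector regression with radial-basis
   kernel (QC-SVRC) is fitted to the pooled-QC intensities versus
   injection order, and every sample is normalized to the drift curve:
   x' = x · median(QC)/f(t). Hyperparameters follow fixed rules
   (ε = 2.5 % of the QC median, C = QC median, γ ∈ [2⁻³ … 2⁹] by 10-fold
   RMSECV). Between-batch offsets are removed by equalizing per-feature
   QC medians; blank-dominated background features and features with
   QC RSD > 15 % are dropped.
3. **Preprocessing** (`uromet.preprocessing`) — multiplicative scatter
   correction against the median QC profile, then Pareto scaling
   (mean-center, divide by √sd) with train-frozen statistics.
4. **PLS-DA** (`uromet.plsda`) — univariate-response NIPALS partial least
   squares on a 0/1 class coding, latent variables chosen by
   leave-one-patient-out RMSECV (or fixed, conventionally 3), feature
   screening by Variable Importance in Projection (VIP > 3), and refit
   on the selected panel.
5. **Diagnostics** (`uromet.diagnostics`) — sensitivity, specificity and
   accuracy with Clopper-Pearson exact 95 % CIs; positive/negative
   likelihood ratios with log-method CIs; rank-sum AUROC; and negative/
   positive predictive values re-evaluated by Bayes' rule at external
   recurrence-risk prevalences.
6. **Longitudinal monitoring** (`uromet.longitudinal`) — per-patient
   predicted-y trajectories during surveillance and a trend flag
   (Spearman correlation with visit + threshold crossing).
7. **Synthetic cohorts** (`uromet.synthetic`) — a generator that emulates
   the whole design (two batches, QC every 5 injections, conditioning
   QCs, blanks, smooth drift, batch offsets, constant-CV noise, injected
   class effects, relapse trajectories) and returns the ground truth, so
   every stage is testable without any external data.

## Worked example

```python
from uromet import (SyntheticConfig, generate_cohort, correct_table,
                    run_discriminant_analysis)
from uromet.synthetic import default_assignment
from uromet.diagnostics import format_metrics

config = SyntheticConfig(n_features=150, n_discriminant=20, n_background=8,
                         n_patients_bc=30, n_patients_monitor=6, seed=1)
table, truth = generate_cohort(config)

corrected, report = correct_table(table)
print(report.summary())

assignment = default_assignment(corrected, seed=1)
result = run_discriminant_analysis(corrected, assignment, n_lv_override=3,
                                   vip_threshold=1.5)
print(format_metrics(result.refit_metrics))
```

prints

```
{'n_features': 150, 'n_retained': 142, 'n_removed_rsd': 0,
 'n_removed_blank': 8, 'median_rsd_before': 17.9, 'median_rsd_after': 2.5}
{'sensitivity': '100.0 (85.8-100.0)%', 'specificity': '100.0 (85.8-100.0)%',
 'accuracy': '100.0 (92.6-100.0)%', 'PLR': 'inf', 'NLR': '0.00 (0.00--)',
 'AUROC': '1.00'}
```

Reading: the correction stage removed the 8 planted background features
and cut the median QC relative standard deviation from 17.9 % (raw, with
30 % drift and 10 % technical noise) to 2.5 %; the 3-LV PLS-DA refit on
the VIP-selected panel (which recovered all 20 planted discriminant
features) classifies every validation sample correctly — this synthetic
cohort is deliberately easier than real urine.

The same flow is available from the shell:

```bash
uromet simulate --config config.yaml --out sim/
uromet correct  --in sim/peak_table.csv --out corrected.csv --report report.json
uromet train    --in corrected.csv --lv 3 --vip-threshold 3 --out model.json
uromet monitor  --in corrected.csv --patient M003 --out trajectory.json
```

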