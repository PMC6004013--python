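# Methods

This note documents the statistical procedures `uromet` implements, the
defaults it ships with, what the synthetic cohort generator does and does
not emulate, and the design choices made where more than one reasonable
convention exists.

## Study design assumed

A cohort of patients sampled before tumor resection (class **BC**),
shortly after resection (**CTRL**), and during surveillance between
negative cystoscopies (**MONITOR**). Samples are acquired in one or more
LC-MS batches; each batch opens with conditioning injections of a pooled
QC sample (excluded from analysis), and the same pooled QC is re-injected
at a fixed cadence (every 5 injections by default) to trace instrument
drift. Blank injections identify background features. All samples of one
patient sit in one batch.

## Within-batch drift correction (QC-SVRC)

For each feature and batch, an ε-insensitive support-vector regression
with radial-basis kernel is fitted to (injection order, QC intensity).
Hyperparameters are rule-based, not tuned per study:

- **ε** = 0.025 × median(QC intensities) — the expected instrumental
  precision; QC variation inside ±2.5 % of the median is noise the curve
  should not chase.
- **C** = median(QC intensities) — puts the error penalty on the scale
  of the response.
- **γ** ∈ {2⁻³, 2⁻², …, 2⁹} (13 candidates), chosen by 10-fold RMSECV on
  the QC points; folds are contiguous blocks over injection order so the
  temporal structure is preserved; fewer QCs than folds falls back to
  leave-one-out; ties resolve to the smallest γ (smoothest curve).

Samples are normalized as x′ = x · qc\_ref / f(t) with qc\_ref the batch
QC median and f the fitted curve clipped at a small positive floor. This
form preserves the intensity scale, so the between-batch step stays
well-defined. Features whose QCs cannot support a fit (fewer than 3
finite points, non-positive median) fall back to a constant-median
correction instead of being dropped, keeping feature sets aligned across
batches.

## Between-batch scaling

Each feature in batch k is multiplied by M/m\_k, where m\_k is the
feature's QC median in batch k and M the median of the per-batch QC
medians. After scaling, per-feature QC medians agree exactly across
batches. (The inverse ratio, m\_k/M, would amplify batch differences;
the direction used here is the one that converges.)

## Reliability filters

- **Blank filter**: a feature is background when its median blank
  intensity is at least ⅓ of its median QC intensity (sample-to-blank
  ratio 3, a common contaminant rule). With no blanks the stage is
  skipped with a warning.
- **RSD filter**: features with post-correction QC RSD (sd/mean × 100,
  pooled over batches) strictly above 15 % are removed; a feature at
  exactly 15.0 % is retained. Features with undefined RSD are removed as
  unreliable.

QC trend diagnostics (PCA scores of QC replicates against injection
order, per-feature RSD cumulative distributions) are computed by singular
value decomposition of the mean-centered QC block.

## Preprocessing

Multiplicative scatter correction regresses each sample on the
per-feature **median QC profile** (ordinary least squares x = a + b·ref)
and returns (x − a)/b, removing per-sample offset and gain. The QC
reference is computed from all non-conditioning QC injections: QCs carry
no class or patient information, so the reference is identical in every
cross-validation fold by construction and cannot leak labels. Pareto
scaling then centers each feature and divides by √sd; both statistics
come from training samples only and are frozen before being applied to
validation data (asserted by test).

## PLS-DA

Univariate-response NIPALS with class coding CTRL → 0, BC → 1 and
decision threshold 0.5 (the coding midpoint; predicted y exactly at the
threshold classifies positive). The regression vector is
b = W(PᵀW)⁻¹q. The latent-variable count is either fixed (3 by default,
the conventional choice for cohorts of this size) or taken from the
minimum of the leave-one-patient-out RMSECV curve, ties going to fewer
components. Cross-validation folds are patients: every sample of the
held-out patient is excluded from fitting and the Pareto statistics are
re-estimated inside each fold. A\_max for CV curves is capped at
min(15, rank − 1).

VIP scores follow the standard formula
VIP\_j = √( p · Σ\_a q\_a²‖t\_a‖² (w\_{ja}/‖w\_a‖)² / Σ\_a q\_a²‖t\_a‖² ),
so Σ\_j VIP\_j² = p. Screening keeps features with VIP strictly above 3,
computed on the full-train model; the refit on the selected panel uses
3 LVs. MONITOR samples never enter model fitting.

## Figures of merit

- Proportions (sensitivity, specificity, accuracy) carry Clopper-Pearson
  exact 95 % intervals (beta quantiles; k = 0 pins the lower bound at 0,
  k = n the upper at 100 %). This is the method consistent with every
  printed interval we reproduce, including the closed form
  (α/2)^{1/n} for k = n.
- Likelihood ratios use the log method: exp(ln LR ± 1.96·SE) with the
  standard error of the log ratio from the two binomial arms. fp = 0
  yields an infinite PLR and fn = 0 a zero NLR, both flagged rather than
  continuity-corrected.
- AUROC is the rank-sum (Mann-Whitney) estimator with ties counted ½.
- Predictive values at external prevalences use Bayes' rule:
  NPV = spec(1−p) / [(1−sens)p + spec(1−p)], and symmetrically for PPV.
  These project a validation-set test onto recurrence-risk groups whose
  prior recurrence probabilities (e.g. 15/24/28/61 %) differ from the
  cohort mix.

## Longitudinal monitoring

A patient's trajectory is the predicted-y series ordered by visit.
The trend flag evaluates the post-resection portion only (pre-TURBT BC
samples are excluded — surveillance asks whether the profile drifts
*back* toward BC): Spearman ρ of y against visit, with
`rising_toward_BC` when ρ ≥ 0.6 and the series ends within 0.1 of the
threshold, `stable` when |ρ| < 0.6 with no crossing, `inconsistent`
otherwise, and the flag withheld below 3 points. Spearman was chosen
because the shape of a recurrence drift is unknown; only monotonicity is
assumed.

## Synthetic cohort generator

Per feature f: baseline b\_f ~ log-normal; per batch, a smooth drift
d(t) = 1 + amplitude · c(t) with c a random cubic in normalized
injection order scaled to max |c| = 1, and a batch factor 2^u,
u ~ U(−r, r). A study intensity is
b\_f · e\_f(class) · d(t) · 2^u · η with η mean-one log-normal noise of
constant CV (so QC RSD is the natural quality metric and variance is
heteroscedastic in the absolute scale). Class effects act on the log2
scale, symmetric up/down with equal probability. QCs are the pooled
baseline profile (no class effect) under the same drift/batch/noise;
blanks carry only the designated background features. Relapsing MONITOR
patients interpolate e\_f linearly from the CTRL level to the BC level,
reaching it at the recurrence visit. Defaults (30 % drift amplitude,
10 % noise CV, ±0.5 log2 batch range) put the raw median QC RSD near
20 %, which is what a well-behaved but drifting instrument produces, so
the correction stage has realistic work to do.

**Dynamic range.** `baseline_log_sigma` defaults to 0.35 (ln scale,
roughly a four-fold 95 % baseline range). This is deliberately narrower
than a real untargeted peak table, which spans orders of magnitude.
Under Pareto scaling a feature's leverage in the PLS model grows with
√intensity, so class effects injected uniformly at random across a
wide-dynamic-range table would concentrate VIP on the abundant markers
and low-abundance markers would fall below the VIP > 3 screen. The
narrow default keeps the generator's injected effects recoverable —
which is what makes end-to-end ground-truth tests meaningful — at the
cost of realism in intensity spread. Consequence for interpretation:
passing recovery tests show the screening machinery is correct, not that
VIP > 3 would recover low-abundance biomarkers in real data.

**Other non-goals** of the generator: chromatographic peak shapes,
co-elution, adduct/isotope structure, biological between-subject
variance beyond the class effect, and missing-value mechanisms (missing
data is supported by the pipeline but not injected by default).

## Problem sizes in the shipped checks

The test-suite and acceptance-script cohorts are scaled to the minimum
that exercises each property: drift-correction checks use tens of
features (the SVR grid search is per feature × batch; conclusions are
medians over features and do not depend on feature count), VIP-recovery
checks use the full 1000-feature/50-marker configuration with drift and
batch perturbations disabled (those have their own checks), and the
acceptance pipeline runs 150 features over two batches, 30 BC/CTRL
patient pairs and 6 monitored patients.

## Known limitations

- The trend flag's ρ ≥ 0.6 / margin 0.1 defaults are heuristics; no
  alarm-threshold optimization against cystoscopy dates is attempted.
- Degenerate likelihood ratios are reported as ∞/0 with flags; users
  comparing across studies may prefer continuity corrections.
- The between-batch step assumes every batch contains QCs; batches
  without QCs are an error, not imputed.
- No imputation of missing intensities; missingness survives I/O and is
  ignored by medians where possible.
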