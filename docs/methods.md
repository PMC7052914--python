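# Methods

## Problem and endpoint

The package models the risk that a lung-cancer radiotherapy patient develops
radiation pneumonitis of CTCAE grade ≥2 (symptoms requiring medical
intervention) as a function of germline SNP genotypes, with clinical and
dosimetric covariates carried along unpenalized. The endpoint is binary:
`endpoint = (rp_grade >= 2)`.

## Dosage encoding

Array calls are encoded reference-relative against GRCh37. For a biallelic
site with reference allele REF and designated alternative ALT, each allele of
a diploid call contributes 1 if it equals ALT and 0 otherwise (REF or any
other allele); the site value is the sum, an integer 0–2. Consequences that
the tests pin down:

* `(REF,ALT)` and `(ALT,REF)` both encode 1 (order symmetric, phasing
  ignored);
* an off-reference allele is encoding noise, not missingness: `(ALT, other)`
  → 1, `(other, other)` → 0;
* a missing call propagates as missing and is later mean-imputed per site.

Alleles are compared as literal strings; there is no strand flipping or
allele harmonisation, no imputation and no rsID resolution. The reading that
an off-reference *allele* (rather than the whole site) scores 0 is the only
one consistent with summing two per-allele values; the alternative (zeroing
the site) is a one-line change in `encode_site`.

## Quality control

Per-site filters, each computed on the unfiltered column so that filter order
cannot change the surviving set: mean GenCall < 0.7 (skipped with a warning
when scores are absent), missingness > 0.05, MAF < 0.01, Hardy–Weinberg exact
p < 1e-6, and multi-allelic exclusion (which must precede encoding, since the
encoding presumes one ALT). MAF and HWE use non-missing calls only. The HWE
test is the exact conditional test: given the allele counts, the two-sided
p-value sums the probabilities of all heterozygote counts whose conditional
probability does not exceed the observed one; it is verified in the tests
against an exact-rational enumeration oracle for every genotype triple with
total ≤ 30. Per-sample QC (sample call rate) is intentionally out of scope.
"Mean GenCall" is interpreted per site (mean over samples).

## Clinical screen

Continuous factors → two-sided Mann–Whitney U (exact permutation null when
both samples have n ≤ 12 and no ties, otherwise the normal approximation with
tie and continuity corrections; delegated to `scipy.stats.mannwhitneyu`).
Categorical factors → two-sided Fisher exact test with the point-probability
convention: the sum of the fixed-margins hypergeometric probabilities of all
tables no more probable than the observed one (relative guard 1+1e-7). r×c
tables are enumerated exhaustively over the free cells, with an explicit
capacity error instead of a silent approximation. No multiplicity adjustment
is applied, matching the screening character of the analysis. One screened
factor in the emulated study's published table (chemotherapy/targeted
therapy, printed p = 0.5647) is not reproducible by any Fisher convention on
its printed counts; a Yates-corrected chi-square gives 0.567, which is almost
certainly the test actually used there.

## Penalized model

The core estimator minimizes

    -(1/n) Σᵢ [ yᵢ ηᵢ − log(1 + e^{ηᵢ}) ]  +  λ Σⱼ pfⱼ ( α|βⱼ| + (1−α)/2 βⱼ² )

with η = β₀ + Xβ, by IRLS plus cyclic coordinate descent on internally
standardized columns (mean 0, variance 1 with 1/n normalisation), with an
active-set inner loop and warm starts along a descending λ grid (100 points,
log-spaced from λ_max down to 1e-3·λ_max; λ_max is computed from the
null-model gradient after fitting intercept and exempt covariates).
Penalty factors are per column: 1 for SNP dosages, 0 for covariates, which
therefore are present in every model and never shrunk; the intercept is
always unpenalized. Probabilities are clipped at 1e-5 in the IRLS weights.
Coefficients are returned on the input scale. Fits are verified against an
independent split-variable L-BFGS-B convex solver (objective within 1e-8,
coefficients within 1e-5) and against an unpenalized `statsmodels` logistic
fit at λ = 0, and KKT subgradient conditions are asserted at tolerance 1e-6.

Defaults and their reasons:

* **α = 0.5** — the procedure prescribes a lasso/ridge mixture without fixing
  the mixing; 0.5 is the neutral choice and is exposed everywhere.
* **CV** — stratified 10-fold, binomial deviance loss, both the
  minimum-deviance and 1-SE λ reported; model fitting defaults to the more
  conservative 1-SE rule. The fold-path grid is truncated by an
  early-stopping full-data path (dev-ratio > 0.999 or improvement < 1e-5),
  the reference-algorithm convention, which avoids fitting the dense
  noise-only tail.
* **Stability selection** — 500 bootstrap resamples by default (drawn with
  replacement at full cohort size); a marker is "present" in a bootstrap iff
  its coefficient is nonzero at that bootstrap's λ, and markers present in
  more than half of the bootstraps are selected. Two λ modes: the default
  re-runs CV inside each bootstrap (the literal reading of "a model per
  bootstrap cohort"), with CV folds grouped by original sample index so that
  duplicated draws of one sample never straddle a fold boundary — ungrouped
  folds leak and collapse λ toward dense overfitted models; the fast mode
  fixes the full-data CV λ for all bootstraps.
* **Final model** — refit restricted to the selected markers plus the
  unpenalized covariates, at the min-deviance λ of a CV run on the restricted
  design. Covariate handling at scoring time is configurable: `"fold"`
  absorbs the fitted covariate effects, evaluated at the training-cohort
  covariate means, into the intercept (default — keeps the genotype-only
  score calibrated); `"drop"` refits without covariates.
* **Missing dosages** are mean-imputed per site before fitting (QC caps
  missingness at 5%); constant columns are dropped from a fit with a log
  entry.

## RPI scoring and evaluation

RPI = σ(β₀ + Σ Aᵢ Cᵢ) including the fitted intercept (a probability without
an intercept would not be well defined); classification is strict,
`RPI > 0.5`, with the boundary case negative. Evaluation reports confusion
counts and sensitivity/specificity, rounded only for display (one decimal in
percent, half-up). Cohort splitting is a uniform random partition
(default 90 training / 28 validation for a 118-sample cohort), seeded.

## Synthetic cohorts

`SyntheticSpec` defaults emulate a 118-patient radiotherapy cohort:
covariate distributions follow the published summary statistics (age ≈
N(60, 9) clipped to 36–79, dose ≈ N(61.6, 7), V5–V30 and MLD likewise;
smoker 82%, COPD 34%, surgery 8.5%; histology and stage at the published
proportions), grade ≥2 prevalence ≈ 42%, MAF uniform on [0.01, 0.5],
a five-site causal architecture on the encoded-dosage log-odds scale, 1%
missing calls, GenCall means ≈ Beta(40, 2.5), 0.5% multi-allelic sites and
0.2% off-reference calls. `n_snps` defaults to a desk-scale 5000 (the array
scale of ~700k is reachable but pointless for tests). Genotypes are drawn in
Hardy–Weinberg proportions; `n_hwe_violating` plants heterozygote-excess
sites so the HWE filter has true positives to catch. Off-reference calls and
missingness are injected after the outcome is drawn, so they act purely as
encoding noise; causal sites are drawn among clean biallelic sites so that
parameter recovery is well defined. Covariates are independent of outcome by
default, mirroring the finding that dosimetric factors carry little signal.
`target_prevalence` optionally re-centers the intercept to the drawn MAFs
(the realised Σc·2·MAF varies by ~±1 log-odds between realisations).

What the generator does **not** emulate: linkage disequilibrium (sites are
independent), population stratification, batch effects, genotyping-error
correlation with GenCall score. Passing tests therefore demonstrate the
pipeline's statistical machinery, not performance on real array data, where
LD both helps (tagging) and hurts (selection ambiguity).

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at desk scale, chosen to keep the full suite in
minutes while leaving the conclusions qualitative-stable: planted-recovery
checks at n = 400, p = 200 with effects ±1.5–1.8 and 100 bootstraps in the
fast λ mode; the null control at n = 200, p = 50 with 20 replicates × 30
bootstraps in the literal CV-per-bootstrap mode (grid 50 points down to
0.01·λ_max); the end-to-end held-out check at n = 800 (400 train / 400
validation), p = 500, effects ±2.5–3.5 with prevalence centered at 0.5 — at
the lower end of the effect range the Bayes-optimal classifier itself
achieves only ≈0.82 sensitivity/specificity at the fixed 0.5 threshold, so
the check uses effects where the attainable ceiling clears the asserted 0.8
floor with margin.

## Known limitations and observed behaviour

* **CV-optimal penalties overselect.** With λ chosen for prediction (even by
  the 1-SE rule), stability selection reliably recovers every planted causal
  marker with 100% sign agreement, but retains a handful (typically 2–10) of
  markers spuriously correlated with the outcome in the given realisation —
  bootstrap resamples of the same cohort share those markers, so the >0.5
  rule does not remove them. This is the well-known behaviour of
  prediction-optimal ℓ1 penalties, not a solver defect; the per-bootstrap-CV
  mode reduces it (and empties the selection under the null) but does not
  eliminate it at desk scale.
* **Power at the emulated cohort size.** At 90 training samples against
  thousands of candidate markers, the 1-SE penalty returns the intercept-only
  model even for log-odds effects of 3–4 per allele; the min-deviance rule
  selects a couple of markers, typically spurious. The acceptance script
  reports this honestly (study-scale synthetic validation sensitivity 0.0%,
  specificity 100.0%): a discovery of dozens of stable markers from such a
  cohort implies either much stronger effective signal or a more permissive
  selection than these defaults.
* The exact r×c Fisher enumeration has an explicit capacity budget; very
  large tables need a different tool.
* The coordinate-descent kernel is single-threaded by design.
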