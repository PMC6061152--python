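# Methods

## Study design being modelled

The package reproduces, as reusable software, the analysis pattern of a
two-cohort paediatric study of an adult-derived insulin-resistance (IR)
genetic risk score: a clinical cohort of children/adolescents with
overweight/obesity recruited at an obesity clinic, and a population-based
comparator cohort of similar age, both genotyped on a fixed panel of 53
independent IR-risk SNPs. The question at each trait is whether the
per-individual risk-allele burden associates with the trait under an additive
genetic model, whether per-SNP effects are directionally consistent, and
whether effect sizes differ between cohorts.

## Scores

With effect-allele dosages d_ij ∈ [0, 2] over a J-variant panel and positive
per-allele weights w_j (the panel is oriented so every effect allele is
risk-increasing):

* unweighted: GRS_i = Σ_j d_ij, range 0–2J;
* weighted: GRS^w_i = J · (Σ_j w_j d_ij) / (Σ_j w_j).

The weighted score is "normalised by the sum of the effects"; that literal
normalisation maps scores to [0, 2]. Because the two scores are meant to be
interchangeable in downstream regressions, the default multiplies back by J
(mean-weight normalisation), restoring the allele-count scale: with equal
weights the two scores coincide exactly, and per-allele effect sizes remain
interpretable. The literal [0, 2] variant stays available
(`normalization="unit-scale"`) for sensitivity runs.

Missing dosages: the default rescales the observed sum by J/J_obs(i)
(equivalent to imputing an individual's own mean dosage at unobserved
variants); alternatives are sample-frequency imputation and a strict policy.
Individuals with fewer than `min_fraction` (default 0.9) observed variants
get a missing score.

## Variant QC

* **Hardy–Weinberg.** The exact conditional (Levene–Haldane) test: given the
  allele counts, the heterozygote count h has
  P(h) ∝ n! 2^h / (n_AA! h! n_aa!) over counts of matching parity, and the
  two-sided p sums the probabilities of all configurations no more probable
  than the observed one. Variants are retained when p > `hwe_alpha`
  (default 0.05). A 1-df chi-square alternative is provided. Because the test
  assumes hard genotypes, imputed dosages are hard-called when within
  `hardcall_threshold` (default 0.1) of {0, 1, 2}; if fewer than 90% of an
  individual's samples are hard-callable, the test is recorded as not
  computable and the variant retained by default — mirroring the practice of
  testing HWE on directly genotyped variants before imputation. Both choices
  are configurable because published pipelines differ on the ordering and the
  test flavour.
* **Call rate / imputation quality.** Per-variant call rate ≥ `min_call_rate`
  (default 0.95) and, when info scores are supplied, R² > `min_info`
  (default 0.95). The cohort-level protocols the package models applied
  call-rate thresholds to *samples* (≥98% adults, ≥95% children); sample QC
  is out of scope here, so the thresholds are exposed at the variant level
  and a pre-made sample exclusion list is accepted instead.
* **Strand-ambiguous variants.** A/T and C/G panel variants cannot be
  orientation-checked from allele labels; the default keeps them as-is with a
  warning (appropriate when panel and genotypes share an imputation
  reference), with `drop` and `error` policies selectable.

## Derived indices

* HOMA-IR = glucose [mmol/l] × insulin [pmol/l] / 135 (the constant for
  insulin in pmol/l; a range warning fires if the insulin column looks like
  µU/ml).
* Friedewald LDL = TC − HDL − TG/5 [mmol/l], returned missing with a warning
  above TG 4.5 mmol/l, the conventional validity bound (the source protocols
  are silent; 4.5 mmol/l ≈ 400 mg/dl is the standard cut-off).
* LMS SD scores: z = ((x/M)^L − 1)/(L·S), switching to z = ln(x/M)/S when
  |L| ≤ 1e−7. Reference (L, M, S) grids are data, not code: the published
  Danish BMI and American BP references are user-suppliable CSVs; the repo
  generates smooth synthetic references for testing. Age interpolation is
  linear with no extrapolation outside the grid span.
* Blood pressure: mean of the last two of up to three readings; a single
  reading is used as-is and flagged.
* WHR = waist/hip (cm/cm).

## Association battery

Each trait is fit by OLS with an intercept, the GRS (or a SNP dosage) and the
trait's covariates, on complete cases. Classical SEs; two-sided p from
Student t with n − k df. The implementation solves the least-squares problem
directly (numpy) because the calibration suites run tens of thousands of
fits; unit tests pin it against both a normal-equations solve and
statsmodels OLS.

Conventions copied from the modelled study:

* **Transforms.** Seven right-skewed biochemical traits (HOMA-IR, fasting
  insulin, fasting glucose, LDL, HDL, total cholesterol, triacylglycerol) are
  log10-transformed for inference; the reported p comes from the transformed
  fit while β and SE come from the untransformed fit on the identical case
  set, keeping effect sizes in clinical units. HbA1c, WHR, the SD-score
  traits and the DXA fat percentages are analysed untransformed. A normality
  screen is deliberately not applied — the trait list is fixed, as in the
  source analysis.
* **Adjustments.** Age + sex for the biochemical traits, HbA1c, WHR and the
  DXA traits; DXA traits additionally adjusted for scanner type (a scanner
  factor with a single level is dropped as uninformative). SD-score traits
  are already sex/age-standardised and enter unadjusted.
* **FDR.** Benjamini–Hochberg step-up at q = 0.10, family = the 16-trait
  battery within one cohort (the report's column structure); a pooled family
  is available.
* **Directionality.** Signs of the per-SNP βs are compared with the
  hypothesised direction (IR-increasing alleles: higher HOMA-IR/insulin/TG,
  lower HDL) by an exact binomial test at p₀ = 0.5, two-sided by the
  minimum-likelihood rule (identical to doubling the tail at p₀ = 0.5,
  capped at 1).
* **Between-cohort comparison.** (β₁ − β₂)/√(SE₁² + SE₂²) against the
  standard normal by default; the phrase "t-test with βs and SEs" leaves the
  df unspecified, and with n ≈ 650–690 per cohort the normal and t forms are
  indistinguishable — a Welch-df t option exists for small groups. Published
  between-cohort p-values computed on unprinted log-scale βs cannot be
  reproduced from printed raw-scale β/SE pairs; the package documents rather
  than chases them.
* **Sensitivity.** The whole battery re-runs excluding participants flagged
  for IR-influencing conditions/medication, and the report bundle includes a
  paired diff of the two runs.

## Synthetic data generator

The generator's defaults are the study conditions: cohort sizes 689/675,
53 variants with MAF ~ U(0.05, 0.5), panel weights |N(0.02, 0.01)|
(magnitudes of per-allele fasting-insulin effects in large GWAS), ages
uniform on 6–18 y, and trait location/scale anchored to the published cohort
medians and IQRs (e.g. clinical fasting insulin median 115 pmol/l vs 61.24
population; BMI SDS 2.92 vs 0.34). Right-skewed biochemistry is log-normal:
the latent trait is built on the log10 scale — μ = log10(median),
σ = log10(q3/q1)/1.349 — so the battery's log10 analysis is exactly correctly
specified; other traits are normal. Genotypes are Hardy–Weinberg (Binomial(2,
MAF)), optionally smeared with clipped Gaussian noise to emulate imputed
dosages and thinned by a missingness rate.

Effects are planted additively on the generation scale:
latent = μ_cohort + β·(GRS − mean) + γ_age(age − 12) + γ_sex(sex − ½) + ε.
Default planted effects are zero (a null study); `table2_planted_effects()`
supplies the published clinical-cohort magnitudes converted to the
generation scale (a raw effect b on a log-normal trait with median m becomes
b/(m ln 10) in log10 units). Modest default covariate effects (e.g. +0.012
log10-insulin/year) give the adjustments something real to do.

Raw measurements are emitted so every derivation path is exercised end to
end: glucose and insulin (HOMA-IR), HDL/TG and a latent "true LDL" from which
total cholesterol is assembled as LDL + HDL + TG/5 — making the Friedewald
derivation exact and the derived LDL positive by construction (the total
cholesterol median is therefore ≈0.3 mmol/l below its published anchor, a
deliberate trade for internal consistency); WHR × hip → waist; BMI and BP
SD-score latents pushed through the synthetic LMS references with
inverse-LMS, so the derivation stage recovers them; triplicate BP readings
with 2 mmHg noise. Per-trait availability matches the published per-trait
ns (notably DXA on 391/689 clinical and 44/675 population samples), and 29
clinical participants carry the exclusion flag.

What the generator does **not** emulate: linkage disequilibrium between panel
SNPs (the panel is built from independent loci), family/population structure,
genotyping batch effects, puberty-stage effects (the source analysis adjusted
for age only), cross-trait residual correlation beyond what the shared GRS
and the LDL→TC construction induce, and assay detection limits. Passing
calibration tests therefore demonstrate correctness of the estimators under
the assumed additive model, not robustness to those real-data features.

## Numerical choices

* HWE exact test: computed with log-gamma weights normalised by the maximum;
  configurations enter the two-sided sum when their probability is ≤ the
  observed one within relative tolerance 1e−12 (float-safe tie handling).
  Verified against exact integer enumeration for all tables with N ≤ 50.
* OLS: `numpy.linalg.lstsq`; rank checked first and rank-deficient designs
  rejected naming the collinear columns; a perfect fit yields zero SEs and
  NaN t/p rather than dividing by zero.
* LMS: L→0 switch at |L| ≤ 1e−7; generator clips latent SD scores at ±6 so
  the inverse transform stays in its domain.
* Dosage serialisation: 4 decimals in VCF/TSV; round-tripped scores agree
  within 5e−3 on a 53-SNP panel.
* Seeds: one master seed per run; `SeedSequence.spawn` gives each component
  an independent substream, so adding a stage never shifts another's draws.

## Problem sizes in the calibration suites

The statistical acceptance checks run at: 2000 simulated null datasets
(n = 700) for the type-I error of the GRS association; 500 null 16-trait
batteries (n = 680) for FDR-level control; and 500 replicates (n = 680) of a
planted HDL-like effect (β = −0.008 per allele, residual SD matched to the
published IQR) for bias, asserted as |bias| < 0.2·SE. These sizes give
binomial/Monte-Carlo standard errors comfortably inside the asserted bands
while keeping the default test run quick. The calibration loops disable the
per-trait availability thinning so every fit is well-posed at these ns.

## Known limitations

* Sample-level QC (duplicates, relatedness, ancestry outliers, sex checks)
  is not implemented; supply a pre-made exclusion list.
* Multiallelic VCF records and strand-flipped (complement-matching)
  genotypes are rejected rather than resolved.
* The heterogeneity test uses summary statistics only; it does not model
  covariance between cohorts (cohorts are assumed independent).
* The shipped LMS references are synthetic; real SD scores require the
  published national reference tables as CSVs.
* The weighted/unweighted score correlation depends on the panel's weight
  dispersion; under the default weight distribution it is
  Σwv/√(Σv·Σw²v) ≈ 0.85–0.95 across panels (v = 2·MAF·(1−MAF)), which the
  tests check against that closed form rather than against a fixed round
  number.
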