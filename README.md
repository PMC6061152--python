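# irgrs — insulin-resistance genetic risk scores for two-cohort child studies

`irgrs` is a tested, reusable implementation of the analysis used to ask
whether an adult-derived insulin-resistance (IR) genetic risk score already
associates with IR and related metabolic traits in children and adolescents.
It is aimed at genetic epidemiologists who have (a) genotype dosages for a
fixed panel of risk SNPs, (b) a clinical phenotype table, and (c) a two-cohort
design (here: an obesity-clinic sample vs a population-based sample) — or who
want to rehearse and power such an analysis on realistic synthetic data.

## What it computes

**Scores.** For a panel of J risk SNPs with effect-allele dosages
d<sub>ij</sub> ∈ [0, 2] and per-allele weights w<sub>j</sub> > 0:

- unweighted GRS: GRS<sub>i</sub> = Σ<sub>j</sub> d<sub>ij</sub>
- weighted GRS: GRS<sup>w</sup><sub>i</sub> = J · Σ<sub>j</sub> w<sub>j</sub> d<sub>ij</sub> / Σ<sub>j</sub> w<sub>j</sub>

The weighted score is normalised by the sum of the effects and (by default)
rescaled to the 0–2J allele-count scale so the two scores are directly
comparable; a literal [0, 2] normalisation is available via
`normalization="unit-scale"`. Missing dosages are proportionally rescaled,
frequency-imputed or treated strictly.

**QC.** Variant-level filters: exact conditional (Levene–Haldane)
Hardy–Weinberg test on hard calls (retain p > 0.05), call rate, and an
imputation-quality (R²) threshold. A chi-square HWE variant is available.

**Derived indices.** HOMA-IR = glucose[mmol/l] × insulin[pmol/l] / 135;
Friedewald LDL = TC − HDL − TG/5 (invalid above TG 4.5 mmol/l); WHR;
mean-of-last-two blood-pressure readings; and LMS-based SD scores
z = ((x/M)<sup>L</sup> − 1)/(L·S) interpolated from sex/age reference grids.

**Associations.** Additive-model OLS of each trait on the GRS (or on each
SNP's dosage), age/sex-adjusted where conventional and scanner-adjusted for
DXA traits. Right-skewed traits are log10-transformed for inference while
effect sizes and SEs are reported from the untransformed fit. The battery
adds Benjamini–Hochberg FDR (q = 0.10) per cohort, a between-cohort
effect-size comparison (β₁ − β₂)/√(SE₁² + SE₂²), and an exact two-sided
binomial test of per-SNP directional consistency.

**Simulator.** A two-cohort generator calibrated to the published cohort
medians/IQRs (log-normal biochemistry, SD-score anthropometrics routed
through synthetic LMS references, per-trait availability, a medication
exclusion flag) with plantable per-GRS or per-SNP effects — every stage of
the pipeline is testable without access to the original cohort data.

## Worked example

Simulate the default two-cohort study (689 clinical / 675 population
children, 53 SNPs) with the published clinical-cohort effect magnitudes
planted, then run the full battery:

```python
from irgrs.pipeline import PipelineConfig, run_pipeline
from irgrs.simulate import SimulationConfig, table2_planted_effects

cfg = PipelineConfig(
    simulate=SimulationConfig(planted_effects=table2_planted_effects()),
    seed=1,
)
res = run_pipeline(cfg, outdir="out")
print(res.main_table.query("trait in ['homa_ir','hdl','fat_pct_legs']"))
```

which prints (abridged):

```
    cohort        trait   n      beta       se  p_report    p_fdr  heterogeneity_p
  clinical      homa_ir 689   0.08117  0.02938  0.001736  0.00926         0.005321
  clinical          hdl 682 -0.005795 0.002776   0.04397   0.1407           0.3369
  clinical fat_pct_legs 411   -0.2123  0.05645 0.0001945 0.003112           0.2448
population      homa_ir 675 -0.005971  0.01071     0.847    0.952         0.005321
population          hdl 630 -0.009654 0.002906  0.001134  0.01814           0.3369
population fat_pct_legs  42   0.07381   0.2394    0.7596    0.952           0.2448
```

Read: each extra risk allele raises clinical-cohort HOMA-IR by ≈0.08 units
(log10-fit p = 1.7 × 10⁻³, FDR-adjusted 9.3 × 10⁻³) and lowers HDL in both
cohorts, while the small population DXA subset (n = 42) is, as in the real
design, underpowered. The per-SNP directionality summary for HDL in the same
run finds 34 of 49 surviving SNPs effect-negative (exact binomial
p = 9.4 × 10⁻³).

The same pipeline runs from the shell:

```bash
irgrs simulate --seed 1 --outdir study/         # VCF + TSVs + manifest
irgrs score --vcf study/genotypes.vcf --weights study/weights.tsv --out grs.tsv
irgrs all --seed 1 --outdir report/             # full battery + report bundle
```

File-based inputs (VCF with a `DS` dosage field or a TSV dosage matrix,
a weights TSV, a phenotype TSV and LMS reference CSVs) are configured through
the same YAML config; see `PipelineConfig`.

## Layout

| module | contents |
| --- | --- |
| `irgrs.panel` | SNP weight table (`VariantRecord`, `WeightTable`) |
| `irgrs.genotypes` | VCF/TSV dosage input, effect-allele alignment |
| `irgrs.qc` | exact/χ² HWE tests, call-rate & info filters, QC report |
| `irgrs.grs` | unweighted and weighted score construction |
| `irgrs.phenotypes` | HOMA-IR, Friedewald LDL, LMS SD scores, BP, WHR |
| `irgrs.association` | OLS battery, directionality, heterogeneity, BH FDR |
| `irgrs.simulate` | two-cohort study generator and synthetic references |
| `irgrs.pipeline` / `irgrs.cli` | orchestration, report bundle, `irgrs` CLI |

See `docs/methods.md` for the statistical model, default parameters and
known limitations.
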