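"""Two-cohort genotype-phenotype simulator.

Emulates the design the analysis pipeline expects: a clinical cohort of
children/adolescents with overweight/obesity and a population-based comparator
cohort, genotyped on a fixed risk-SNP panel, with

* Hardy-Weinberg genotypes at configurable allele frequencies (optionally
  smeared into imputation-style dosages and thinned by missingness);
* traits anchored to the published cohort medians/IQRs (log-normal for the
  right-skewed biochemical traits, normal otherwise), generated additively
  as trait = alpha_cohort + beta * GRS + gamma_age * age + gamma_sex * sex + e
  on the generation scale (log10 for log-normal traits, so a log10 analysis
  is exactly correctly specified);
* raw measurements for the derived indices: glucose/insulin (-> HOMA-IR),
  HDL/triacylglycerol/true LDL (-> total cholesterol by construction, so the
  Friedewald derivation is exact and always positive), waist/hip (-> WHR),
  BMI through a synthetic LMS growth reference, and triplicate BP readings
  through synthetic BP references;
* per-trait availability matching the published per-trait sample sizes
  (notably DXA on a clinical subset and a small population subset), plus a
  medication/condition exclusion flag on a configurable number of clinical
  participants.

Everything is driven by a single integer seed; per-component substreams are
spawned from it so adding one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .panel import VariantRecord, WeightTable
from .phenotypes import LMSReference, inverse_lms

Model = Literal["normal", "lognormal"]
CohortName = Literal["clinical", "population"]

_NORMAL_IQR = 1.3489795003921634  # q75 - q25 of the standard normal

#: (median, q1, q3) anchors per trait and cohort, and the generation-scale model.
#: Medians/IQRs follow the published clinical characteristics of the two
#: child cohorts (clinical = obesity-clinic sample, population = school-based).
TRAIT_ANCHORS: dict[str, dict] = {
    "fasting_glucose": {"model": "lognormal",
                        "clinical": (5.10, 4.9, 5.4), "population": (4.97, 4.8, 5.2)},
    "fasting_insulin": {"model": "lognormal",
                        "clinical": (115.0, 77.0, 166.5), "population": (61.24, 45.5, 83.9)},
    "hba1c": {"model": "normal",
              "clinical": (34.0, 33.0, 37.0), "population": (35.0, 33.0, 36.0)},
    "ldl": {"model": "lognormal",
            "clinical": (2.50, 2.1, 3.0), "population": (2.10, 1.8, 2.5)},
    "hdl": {"model": "lognormal",
            "clinical": (1.20, 1.0, 1.4), "population": (1.50, 1.3, 1.7)},
    "triacylglycerol": {"model": "lognormal",
                        "clinical": (0.90, 0.7, 1.3), "population": (0.60, 0.5, 0.9)},
    "bmi_sds": {"model": "normal",
                "clinical": (2.92, 2.5, 3.3), "population": (0.34, -0.4, 1.0)},
    "whr": {"model": "normal",
            "clinical": (0.98, 0.9, 1.0), "population": (0.83, 0.8, 0.9)},
    "sbp_sds": {"model": "normal",
                "clinical": (1.55, 0.8, 2.6), "population": (1.57, 0.8, 2.6)},
    "dbp_sds": {"model": "normal",
                "clinical": (0.59, 0.1, 1.2), "population": (0.42, -0.1, 0.9)},
    "fat_pct_total": {"model": "normal",
                      "clinical": (43.96, 40.4, 47.6), "population": (25.26, 22.2, 31.5)},
    "fat_pct_torso": {"model": "normal",
                      "clinical": (45.18, 40.5, 49.9), "population": (20.27, 16.9, 28.5)},
    "fat_pct_legs": {"model": "normal",
                     "clinical": (45.63, 42.3, 48.8), "population": (31.00, 27.5, 36.6)},
    "fat_pct_arms": {"model": "normal",
                     "clinical": (46.02, 42.4, 50.0), "population": (31.76, 24.9, 36.4)},
}

#: Per-trait availability (observed n out of 689 clinical / 675 population),
#: mirroring the published per-trait sample sizes.
AVAILABILITY: dict[str, tuple[int, int]] = {
    "fasting_glucose": (689, 675),
    "fasting_insulin": (689, 675),
    "hba1c": (686, 636),
    "ldl": (680, 635),
    "hdl": (680, 635),
    "triacylglycerol": (680, 635),
    "bmi_sds": (689, 675),
    "whr": (664, 672),
    "sbp_sds": (660, 642),
    "dbp_sds": (660, 642),
    "fat_pct_total": (391, 44),
    "fat_pct_torso": (391, 44),
    "fat_pct_legs": (391, 44),
    "fat_pct_arms": (391, 44),
}
_BASE_N = {"clinical": 689, "population": 675}

#: Default covariate effects (gamma_age per year, gamma_sex for female) on the
#: generation scale.  SD-score traits are already age/sex-standardised, so
#: their covariate effects are zero.
COVARIATE_EFFECTS: dict[str, tuple[float, float]] = {
    "fasting_insulin": (0.012, 0.02),
    "fasting_glucose": (0.001, -0.005),
    "triacylglycerol": (0.004, 0.0),
    "hdl": (-0.003, 0.01),
    "ldl": (0.002, 0.01),
    "hba1c": (-0.05, 0.1),
    "whr": (-0.002, -0.02),
    "fat_pct_total": (0.2, 6.0),
    "fat_pct_torso": (0.2, 5.0),
    "fat_pct_legs": (0.2, 7.0),
    "fat_pct_arms": (0.2, 6.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the two-cohort generator (defaults emulate the study design)."""

    n_clinical: int = 689
    n_population: int = 675
    n_variants: int = 53
    maf_range: tuple[float, float] = (0.05, 0.5)
    mafs: Optional[np.ndarray] = None
    weight_mean: float = 0.02
    weight_sd: float = 0.01
    dosage_noise_sd: float = 0.0
    missing_rate: float = 0.002
    age_range: tuple[float, float] = (6.0, 18.0)
    female_fraction: float = 0.5
    #: planted per-GRS-unit effects on the generation scale
    #: (log10 units for log-normal traits); values may be a float (both
    #: cohorts) or a {"clinical": x, "population": y} mapping.
    planted_effects: dict[str, Union[float, dict]] = dc_field(default_factory=dict)
    #: per-variant effects for one trait: {"trait": name, "betas": array}
    planted_snp_effects: Optional[dict] = None
    #: override the generation model of individual traits
    trait_models: dict[str, Model] = dc_field(default_factory=dict)
    covariate_effects: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(COVARIATE_EFFECTS))
    use_availability: bool = True
    n_excluded_clinical: int = 29
    n_excluded_population: int = 0
    scanner_idxa_fraction: dict = dc_field(
        default_factory=lambda: {"clinical": 0.45, "population": 0.9})
    scanner_offset: float = 0.8  # additive iDXA offset on fat percentages
    bp_reading_sd: float = 2.0  # mmHg noise per individual BP reading

    def __post_init__(self) -> None:
        if self.n_clinical <= 0 or self.n_population < 0:
            raise ValueError("cohort sizes must be positive")
        if self.n_variants <= 0:
            raise ValueError("at least one variant is required")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
                raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


# --------------------------------------------------------------------------- #
# panel and genotypes
# --------------------------------------------------------------------------- #

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def make_panel(n_variants: int, rng: np.random.Generator,
               weight_mean: float = 0.02, weight_sd: float = 0.01) -> WeightTable:
    """A synthetic risk-SNP panel (stand-in for the study's unpublished panel).

    Weights are |N(weight_mean, weight_sd)| — magnitudes in the range of
    per-allele fasting-insulin effects from large GWAS — oriented positive
    (risk-allele convention).  Alleles are drawn non-palindromic so strand
    alignment is unambiguous.
    """
    variants = []
    for j in range(n_variants):
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        w = abs(rng.normal(weight_mean, weight_sd))
        variants.append(
            VariantRecord(
                variant_id=f"rs{100001 + j}",
                chrom=str(j % 22 + 1),
                pos=1_000_000 + 10_000 * j,
                effect_allele=ea,
                other_allele=oa,
                weight=max(w, 1e-4),
                gene=f"GENE{j + 1}",
            )
        )
    return WeightTable(variants)


def draw_mafs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.mafs is not None:
        if len(cfg.mafs) != cfg.n_variants:
            raise ValueError("explicit mafs length must equal n_variants")
        return cfg.mafs
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, cfg.n_variants)


def simulate_genotypes(
    n_samples: int,
    mafs: np.ndarray,
    panel: WeightTable,
    rng: np.random.Generator,
    dosage_noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes (two Bernoulli allele draws per individual).

    Effect-allele dosages; optional centred Gaussian noise (clipped to [0, 2])
    emulates imputation uncertainty, and cells go missing at ``missing_rate``.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    if len(mafs) != len(panel):
        raise ValueError("mafs length must match panel size")
    geno = rng.binomial(2, mafs, size=(n_samples, len(mafs))).astype(float)
    if dosage_noise_sd > 0:
        geno = np.clip(geno + rng.normal(0.0, dosage_noise_sd, geno.shape), 0.0, 2.0)
    missing = rng.random(geno.shape) < missing_rate
    ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=ids,
        variants=list(panel.variants),
        dosage=geno,
        missing=missing,
    )


# --------------------------------------------------------------------------- #
# synthetic growth / blood-pressure references
# --------------------------------------------------------------------------- #

def make_bmi_reference(age_lo: float = 5.0, age_hi: float = 19.0,
                       step: float = 0.5) -> LMSReference:
    """Synthetic BMI-for-age LMS reference (smooth analytic grid, both sexes)."""
    rows = []
    ages = np.arange(age_lo, age_hi + step / 2, step)
    for sex, m_off in (("male", 0.3), ("female", 0.0)):
        for a in ages:
            rows.append({"sex": sex, "age_years": float(a),
                         "L": -1.6 + 0.02 * a,
                         "M": 15.5 + 0.45 * a + m_off,
                         "S": 0.11})
    return LMSReference(pd.DataFrame(rows))


def make_bp_reference(kind: Literal["sbp", "dbp"], age_lo: float = 5.0,
                      age_hi: float = 19.0, step: float = 0.5) -> LMSReference:
    """Synthetic sex/age BP reference on the LMS form with L = 1 (no skew)."""
    rows = []
    ages = np.arange(age_lo, age_hi + step / 2, step)
    for sex, m_off in (("male", 1.0), ("female", 0.0)):
        for a in ages:
            if kind == "sbp":
                m, s = 92.0 + 1.1 * a + m_off, 0.085
            else:
                m, s = 55.0 + 0.7 * a + m_off, 0.10
            rows.append({"sex": sex, "age_years": float(a), "L": 1.0, "M": m, "S": s})
    return LMSReference(pd.DataFrame(rows))


# --------------------------------------------------------------------------- #
# phenotypes
# --------------------------------------------------------------------------- #

def _anchor_params(trait: str, cohort: CohortName, model: Model) -> tuple[float, float]:
    med, q1, q3 = TRAIT_ANCHORS[trait][cohort]
    if model == "lognormal":
        return np.log10(med), (np.log10(q3) - np.log10(q1)) / _NORMAL_IQR
    return med, (q3 - q1) / _NORMAL_IQR


def _planted_beta(cfg: SimulationConfig, trait: str, cohort: CohortName) -> float:
    val = cfg.planted_effects.get(trait, 0.0)
    if isinstance(val, dict):
        return float(val.get(cohort, 0.0))
    return float(val)


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    cfg: SimulationConfig,
    cohort: CohortName,
    rng: np.random.Generator,
    bmi_reference: Optional[LMSReference] = None,
    sbp_reference: Optional[LMSReference] = None,
    dbp_reference: Optional[LMSReference] = None,
) -> pd.DataFrame:
    """Raw phenotype table for one cohort given its genotypes.

    Traits are built additively on the generation scale from the centred
    unweighted risk-allele count, age (centred at 12 y) and sex, then mapped
    to raw measurements (10^latent for log-normal traits; inverse-LMS for BMI
    and BP SD scores; waist = WHR x hip).
    """
    n = matrix.n_samples
    age = rng.uniform(*cfg.age_range, n)
    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    sex_c = (sex == "female").astype(float) - 0.5
    age_c = age - 12.0

    # GRS used for effect planting: observed dosages, column-mean imputed
    obs = ~matrix.missing
    col_mean = np.where(obs.sum(0) > 0, (matrix.dosage * obs).sum(0) / np.maximum(obs.sum(0), 1), 0)
    filled = np.where(obs, matrix.dosage, col_mean)
    grs = filled.sum(axis=1)
    grs_c = grs - grs.mean()

    idxa = rng.random(n) < cfg.scanner_idxa_fraction.get(cohort, 0.5)
    scanner = np.where(idxa, "idxa", "prodigy")

    n_excl = cfg.n_excluded_clinical if cohort == "clinical" else cfg.n_excluded_population
    exclusion = np.zeros(n, dtype=bool)
    if n_excl > 0:
        exclusion[rng.choice(n, size=min(n_excl, n), replace=False)] = True

    out = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "cohort": cohort,
            "age": age,
            "sex": sex,
            "scanner_id": scanner,
            "exclusion_flag": exclusion,
        }
    )

    latents: dict[str, np.ndarray] = {}
    for trait, spec in TRAIT_ANCHORS.items():
        model: Model = cfg.trait_models.get(trait, spec["model"])
        mu, sigma = _anchor_params(trait, cohort, model)
        beta = _planted_beta(cfg, trait, cohort)
        g_age, g_sex = cfg.covariate_effects.get(trait, (0.0, 0.0))
        lat = mu + beta * grs_c + g_age * age_c + g_sex * sex_c \
            + sigma * rng.standard_normal(n)
        if cfg.planted_snp_effects and cfg.planted_snp_effects.get("trait") == trait:
            betas_j = np.asarray(cfg.planted_snp_effects["betas"], dtype=float)
            if betas_j.shape != (matrix.n_variants,):
                raise ValueError("planted_snp_effects betas length mismatch")
            lat = lat + (filled - filled.mean(0)) @ betas_j
        latents[trait] = lat

    # raw biochemical measurements
    for trait in ("fasting_glucose", "fasting_insulin", "hdl", "triacylglycerol", "ldl"):
        model = cfg.trait_models.get(trait, TRAIT_ANCHORS[trait]["model"])
        out[trait] = 10.0 ** latents[trait] if model == "lognormal" else latents[trait]
    out["hba1c"] = latents["hba1c"]
    # total cholesterol assembled Friedewald-consistently from its components
    out["total_chol"] = out["ldl"] + out["hdl"] + out["triacylglycerol"] / 5.0
    out = out.drop(columns=["ldl"])  # the pipeline re-derives LDL

    # anthropometrics through the synthetic references
    bmi_ref = bmi_reference or make_bmi_reference()
    z_bmi = np.clip(latents["bmi_sds"], -6.0, 6.0)
    L, M, S = bmi_ref.lookup(age, sex)
    out["bmi"] = inverse_lms(z_bmi, L, M, S)
    out["height"] = rng.normal(1.05 + 0.031 * age, 0.07)  # m, for completeness
    out["weight"] = out["bmi"] * out["height"] ** 2

    hip = np.maximum(rng.normal(95.0, 10.0, n), 60.0)
    out["hip"] = hip
    out["waist"] = np.maximum(latents["whr"], 0.5) * hip

    sbp_ref = sbp_reference or make_bp_reference("sbp")
    dbp_ref = dbp_reference or make_bp_reference("dbp")
    for kind, ref in (("sbp", sbp_ref), ("dbp", dbp_ref)):
        z = np.clip(latents[f"{kind}_sds"], -6.0, 6.0)
        L, M, S = ref.lookup(age, sex)
        true_bp = inverse_lms(z, L, M, S)
        for r in (1, 2, 3):
            out[f"{kind}_{r}"] = true_bp + rng.normal(0.0, cfg.bp_reading_sd, n)

    for trait in ("fat_pct_total", "fat_pct_torso", "fat_pct_legs", "fat_pct_arms"):
        vals = latents[trait] + np.where(idxa, cfg.scanner_offset, 0.0)
        out[trait] = np.maximum(vals, 0.5)

    if cfg.use_availability:
        _apply_availability(out, cohort, rng)
    return out


_AVAIL_COLUMNS: dict[str, list[str]] = {
    "fasting_glucose": ["fasting_glucose"],
    "fasting_insulin": ["fasting_insulin"],
    "hba1c": ["hba1c"],
    "hdl": ["hdl", "triacylglycerol", "total_chol"],  # lipid panel measured together
    "whr": ["waist", "hip"],
    "sbp_sds": ["sbp_1", "sbp_2", "sbp_3", "dbp_1", "dbp_2", "dbp_3"],
    "fat_pct_total": ["fat_pct_total", "fat_pct_torso", "fat_pct_legs", "fat_pct_arms"],
}


def _apply_availability(out: pd.DataFrame, cohort: CohortName,
                        rng: np.random.Generator) -> None:
    n = len(out)
    base = _BASE_N[cohort]
    for anchor, cols in _AVAIL_COLUMNS.items():
        n_avail = AVAILABILITY[anchor][0 if cohort == "clinical" else 1]
        frac = n_avail / base
        if frac >= 1.0:
            continue
        miss = rng.random(n) >= frac
        for c in cols:
            if c in out.columns:
                out.loc[miss, c] = np.nan


# --------------------------------------------------------------------------- #
# full study
# --------------------------------------------------------------------------- #

@dataclass
class StudyData:
    panel: WeightTable
    genotypes: GenotypeMatrix  # both cohorts, row-concatenated
    phenotypes: pd.DataFrame
    mafs: np.ndarray
    manifest: dict


def simulate_two_cohort_study(
    cfg: SimulationConfig,
    seed: int,
    outdir: Optional[str | Path] = None,
) -> StudyData:
    """Simulate the full two-cohort study; optionally persist it as files.

    Files written to ``outdir``: ``genotypes.vcf`` (DS dosage field),
    ``phenotypes.tsv``, ``weights.tsv``, synthetic LMS reference CSVs and a
    ``manifest.yaml`` recording every planted parameter and the seed.
    """
    ss = np.random.SeedSequence(seed)
    rng_panel, rng_gc, rng_gp, rng_pc, rng_pp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    panel = make_panel(cfg.n_variants, rng_panel, cfg.weight_mean, cfg.weight_sd)
    mafs = draw_mafs(cfg, rng_panel)

    geno_c = simulate_genotypes(cfg.n_clinical, mafs, panel, rng_gc,
                                cfg.dosage_noise_sd, cfg.missing_rate, "C")
    geno_p = simulate_genotypes(cfg.n_population, mafs, panel, rng_gp,
                                cfg.dosage_noise_sd, cfg.missing_rate, "P")
    overlap = set(geno_c.sample_ids) & set(geno_p.sample_ids)
    if overlap:
        raise ValueError(f"overlapping sample ids across cohorts: {sorted(overlap)[:5]}")

    pheno_c = simulate_phenotypes(geno_c, cfg, "clinical", rng_pc)
    pheno_p = simulate_phenotypes(geno_p, cfg, "population", rng_pp)
    pheno = pd.concat([pheno_c, pheno_p], ignore_index=True)

    genotypes = GenotypeMatrix(
        sample_ids=geno_c.sample_ids + geno_p.sample_ids,
        variants=list(panel.variants),
        dosage=np.vstack([geno_c.dosage, geno_p.dosage]),
        missing=np.vstack([geno_c.missing, geno_p.missing]),
    )

    manifest = {
        "seed": int(seed),
        "n_clinical": cfg.n_clinical,
        "n_population": cfg.n_population,
        "n_variants": cfg.n_variants,
        "mafs": [float(m) for m in mafs],
        "weights": [float(w) for w in panel.weights],
        "dosage_noise_sd": cfg.dosage_noise_sd,
        "missing_rate": cfg.missing_rate,
        "planted_effects": {
            k: ({ck: float(cv) for ck, cv in v.items()} if isinstance(v, dict) else float(v))
            for k, v in cfg.planted_effects.items()
        },
        "n_excluded_clinical": cfg.n_excluded_clinical,
        "scanner_offset": cfg.scanner_offset,
        "synthetic": True,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(genotypes, outdir / "genotypes.vcf")
        pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        panel.to_tsv(outdir / "weights.tsv")
        make_bmi_reference().table.to_csv(outdir / "lms_bmi_synthetic.csv", index=False)
        make_bp_reference("sbp").table.to_csv(outdir / "lms_sbp_synthetic.csv", index=False)
        make_bp_reference("dbp").table.to_csv(outdir / "lms_dbp_synthetic.csv", index=False)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    return StudyData(panel=panel, genotypes=genotypes, phenotypes=pheno,
                     mafs=mafs, manifest=manifest)


def write_vcf(matrix: GenotypeMatrix, path: str | Path, precision: int = 4) -> None:
    """Write a minimal VCF 4.2 with per-sample DS (effect-allele dosage) field.

    REF is the panel's other allele and ALT the effect allele, so the DS field
    counts effect alleles directly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        fmt = f"%.{precision}f"
        for j, v in enumerate(matrix.variants):
            cells = [
                "." if matrix.missing[i, j] else fmt % matrix.dosage[i, j]
                for i in range(matrix.n_samples)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                f"{v.effect_allele}\t.\tPASS\t.\tDS\t" + "\t".join(cells) + "\n"
            )


def table2_planted_effects() -> dict[str, Union[float, dict]]:
    """Planted per-GRS-unit effects of the magnitude reported for the clinical
    cohort, expressed on the generation scale (log10 for log-normal traits).

    Raw-scale effects b on a log-normal trait with median m convert to the
    log10 scale as b / (m ln 10).
    """
    ln10 = np.log(10.0)
    return {
        # raw effects: insulin +2.25 pmol/l, glucose +0.010 mmol/l, HDL -0.008
        "fasting_insulin": {"clinical": 2.25 / (115.0 * ln10), "population": 0.0},
        "fasting_glucose": {"clinical": 0.010 / (5.10 * ln10), "population": 0.0},
        "hdl": {"clinical": -0.008 / (1.20 * ln10), "population": -0.007 / (1.50 * ln10)},
        "sbp_sds": {"clinical": 0.026, "population": 0.0},
        "fat_pct_total": {"clinical": -0.143, "population": 0.0},
        "fat_pct_legs": {"clinical": -0.197, "population": 0.0},
    }
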