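"""End-to-end pipeline: data in (files or simulator), QC, scoring, derived
traits, the association battery, per-SNP effects with directionality, and a
report bundle with an optional sensitivity re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .association import (
    DEFAULT_TRAIT_BATTERY,
    PER_SNP_TRAITS,
    AssociationResult,
    TraitConfig,
    assoc_grs,
    attach_fdr,
    direction_binomial,
    heterogeneity_test,
    per_snp_assoc,
    results_to_frame,
)
from .genotypes import AmbiguousPolicy, GenotypeMatrix, align_to_effect_allele, read_genotypes
from .grs import MissingPolicy, Normalization, compute_grs
from .panel import WeightTable
from .phenotypes import LMSReference, derive_phenotypes
from .qc import QCParams, filter_variants, write_qc_report
from .simulate import (
    SimulationConfig,
    make_bmi_reference,
    make_bp_reference,
    simulate_two_cohort_study,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of (input paths, simulate block)."""

    # file inputs
    genotypes_path: Optional[str] = None
    genotypes_format: Optional[str] = None
    weights_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    lms_bmi_path: Optional[str] = None
    lms_sbp_path: Optional[str] = None
    lms_dbp_path: Optional[str] = None
    sample_exclusion_path: Optional[str] = None  # pre-made sample-level QC list
    # or simulation
    simulate: Optional[SimulationConfig] = None
    seed: int = 0
    # analysis options
    qc: QCParams = dc_field(default_factory=QCParams)
    ambiguous_policy: AmbiguousPolicy = "trust"
    missing_policy: MissingPolicy = "rescale"
    normalization: Normalization = "count-scale"
    min_fraction: float = 0.9
    grs_column: str = "grs_unweighted"
    trait_battery: tuple[TraitConfig, ...] = DEFAULT_TRAIT_BATTERY
    fdr_q: float = 0.10
    heterogeneity_df_mode: str = "normal"
    sensitivity: bool = True

    def __post_init__(self) -> None:
        has_files = self.genotypes_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide exactly one of input paths or a simulate block")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QCParams(**raw["qc"])
        if "trait_battery" in raw and raw["trait_battery"] is not None:
            raw["trait_battery"] = tuple(TraitConfig(**t) for t in raw["trait_battery"])
        return cls(**raw)


@dataclass
class PipelineResult:
    main_table: pd.DataFrame
    per_snp: dict[str, pd.DataFrame]  # trait -> per-cohort per-SNP results
    directionality: pd.DataFrame
    qc_report: pd.DataFrame
    grs: pd.DataFrame
    grs_summary: pd.DataFrame
    forest: pd.DataFrame
    sensitivity_diff: Optional[pd.DataFrame]
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("input")
def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        study = simulate_two_cohort_study(config.simulate, config.seed)
        refs = (make_bmi_reference(), make_bp_reference("sbp"), make_bp_reference("dbp"))
        return study.panel, study.genotypes, study.phenotypes, refs, study.manifest
    panel = WeightTable.from_tsv(config.weights_path)
    matrix = read_genotypes(config.genotypes_path, panel, config.genotypes_format)
    pheno = pd.read_csv(config.phenotypes_path, sep="\t")
    if config.sample_exclusion_path:
        excl = set(pd.read_csv(config.sample_exclusion_path, sep="\t", header=None)[0])
        keep = [i for i, s in enumerate(matrix.sample_ids) if s not in excl]
        matrix = GenotypeMatrix(
            sample_ids=[matrix.sample_ids[i] for i in keep],
            variants=list(matrix.variants),
            dosage=matrix.dosage[keep],
            missing=matrix.missing[keep],
            counted_allele=list(matrix.counted_allele),
            uncounted_allele=list(matrix.uncounted_allele),
        )
        pheno = pheno[~pheno["sample_id"].isin(excl)]
    refs = tuple(
        LMSReference.from_csv(p) if p else None
        for p in (config.lms_bmi_path, config.lms_sbp_path, config.lms_dbp_path)
    )
    manifest = {"seed": config.seed, "inputs": {
        "genotypes": config.genotypes_path, "weights": config.weights_path,
        "phenotypes": config.phenotypes_path}}
    return panel, matrix, pheno, refs, manifest


@_stage("association")
def _run_battery(
    pheno: pd.DataFrame,
    grs: pd.DataFrame,
    config: PipelineConfig,
    drop_excluded: bool,
) -> tuple[pd.DataFrame, dict[str, list[AssociationResult]]]:
    cohorts = list(pd.unique(pheno["cohort"]))
    per_cohort: dict[str, list[AssociationResult]] = {}
    for cohort in cohorts:
        sub = pheno[pheno["cohort"] == cohort]
        results = []
        for cfg_t in config.trait_battery:
            if cfg_t.name not in sub.columns:
                logger.warning("trait %s absent; skipped", cfg_t.name)
                continue
            results.append(
                assoc_grs(sub, grs, cfg_t, config.grs_column, drop_excluded=drop_excluded)
            )
        per_cohort[cohort] = attach_fdr(results, config.fdr_q)

    frames = []
    for cohort, results in per_cohort.items():
        frame = results_to_frame(results)
        frame.insert(0, "cohort", cohort)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)

    # between-cohort effect-size comparison (first two cohorts)
    if len(cohorts) == 2:
        a, b = cohorts
        ra = {r.trait: r for r in per_cohort[a]}
        rb = {r.trait: r for r in per_cohort[b]}
        het = {}
        for trait in ra:
            if trait in rb:
                _, p = heterogeneity_test(
                    ra[trait].beta, ra[trait].se, rb[trait].beta, rb[trait].se,
                    df_mode=config.heterogeneity_df_mode,
                    n1=ra[trait].n, n2=rb[trait].n,
                )
                het[trait] = p
        table["heterogeneity_p"] = table["trait"].map(het)
    return table, per_cohort


@_stage("per_snp")
def _run_per_snp(
    matrix: GenotypeMatrix,
    pheno: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    battery = {t.name: t for t in config.trait_battery}
    per_snp: dict[str, pd.DataFrame] = {}
    direction_rows = []
    cohorts = list(pd.unique(pheno["cohort"]))
    for trait in PER_SNP_TRAITS:
        if trait not in battery or trait not in pheno.columns:
            continue
        cfg_t = battery[trait]
        frames = []
        for cohort in cohorts:
            sub = pheno[pheno["cohort"] == cohort]
            results = per_snp_assoc(matrix, sub, cfg_t)
            frame = results_to_frame(results)
            frame.insert(0, "cohort", cohort)
            frames.append(frame)
            if cfg_t.direction_expected and results:
                signs = [int(np.sign(r.beta)) for r in results if r.beta != 0]
                k, n, p = direction_binomial(signs, cfg_t.direction_expected)
                direction_rows.append(
                    {"trait": trait, "cohort": cohort, "k_consistent": k,
                     "n_snps": n, "p_two_sided": p,
                     "expected_direction": cfg_t.direction_expected}
                )
        per_snp[trait] = pd.concat(frames, ignore_index=True)
    return per_snp, pd.DataFrame(direction_rows)


def render_forest_table(per_snp: pd.DataFrame, panel: WeightTable,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Forest-style table: per SNP and cohort, effect with 95% CI and a
    significance flag, ordered as the panel with nearest-gene labels."""
    if per_snp.empty:
        raise ValueError("no per-SNP results to render")
    genes = {v.variant_id: (v.gene or "") for v in panel}
    order = {v.variant_id: j for j, v in enumerate(panel)}
    out = per_snp.copy()
    out["gene"] = out["predictor"].map(genes)
    out["ci_low"] = out["beta"] - 1.96 * out["se"]
    out["ci_high"] = out["beta"] + 1.96 * out["se"]
    out["significant"] = out["p_report"] < alpha
    out["_order"] = out["predictor"].map(order)
    out = out.sort_values(["_order", "cohort"]).drop(columns="_order")
    cols = ["gene", "predictor", "cohort", "n", "beta", "se",
            "ci_low", "ci_high", "p_report", "significant"]
    return out[cols].reset_index(drop=True)


def plot_forest(forest: pd.DataFrame, path: str | Path) -> None:
    """Basic forest plot of per-SNP effects by cohort."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    snps = forest["predictor"].drop_duplicates().tolist()
    ypos = {s: i for i, s in enumerate(snps)}
    fig, ax = plt.subplots(figsize=(7, max(4, 0.22 * len(snps))))
    colors = {c: col for c, col in zip(sorted(forest["cohort"].unique()),
                                       ("black", "grey", "tab:blue"))}
    for cohort, grp in forest.groupby("cohort"):
        off = 0.2 if cohort == sorted(colors)[0] else -0.2
        y = np.array([ypos[s] for s in grp["predictor"]]) + off
        ax.errorbar(grp["beta"], y,
                    xerr=1.96 * grp["se"], fmt="o", ms=3,
                    color=colors.get(cohort, "black"), label=str(cohort), lw=1)
    ax.axvline(0.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(range(len(snps)))
    labels = [f"{g} ({s})" if g else s for g, s in
              forest.drop_duplicates("predictor")[["gene", "predictor"]].itertuples(index=False)]
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("per-allele effect (95% CI)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    """Run every stage; write the report bundle when ``outdir`` is given."""
    panel, matrix, pheno, (bmi_ref, sbp_ref, dbp_ref), manifest = _load_inputs(config)

    try:
        matrix = align_to_effect_allele(matrix, panel, config.ambiguous_policy)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("align", str(exc)) from exc

    try:
        matrix, qc_report = filter_variants(matrix, config.qc)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    try:
        panel_kept = panel.subset([v.variant_id for v in matrix.variants])
        grs = compute_grs(matrix, panel_kept, config.missing_policy,
                          config.min_fraction, config.normalization)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("score", str(exc)) from exc

    try:
        pheno = derive_phenotypes(pheno, bmi_ref, sbp_ref, dbp_ref)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("derive", str(exc)) from exc

    main_table, _ = _run_battery(pheno, grs, config, drop_excluded=False)
    per_snp, directionality = _run_per_snp(matrix, pheno, config)

    grs_summary = (
        pheno[["sample_id", "cohort"]]
        .merge(grs, on="sample_id")
        .groupby("cohort")[["grs_unweighted", "grs_weighted"]]
        .agg(["mean", "std", "min", "max"])
    )

    forest_trait = "homa_ir" if "homa_ir" in per_snp else next(iter(per_snp), None)
    forest = (render_forest_table(per_snp[forest_trait], panel_kept)
              if forest_trait else pd.DataFrame())

    sensitivity_diff = None
    if config.sensitivity:
        sens_table, _ = _run_battery(pheno, grs, config, drop_excluded=True)
        merged = main_table.merge(sens_table, on=["cohort", "trait"],
                                  suffixes=("_all", "_sens"))
        merged["delta_beta"] = merged["beta_sens"] - merged["beta_all"]
        merged["n_removed"] = merged["n_all"] - merged["n_sens"]
        sensitivity_diff = merged[["cohort", "trait", "n_all", "n_sens", "n_removed",
                                   "beta_all", "beta_sens", "delta_beta",
                                   "p_report_all", "p_report_sens"]]

    manifest = dict(manifest)
    manifest.update({
        "n_variants_after_qc": matrix.n_variants,
        "fdr_q": config.fdr_q,
        "grs_column": config.grs_column,
        "sensitivity": config.sensitivity,
    })

    result = PipelineResult(
        main_table=main_table,
        per_snp=per_snp,
        directionality=directionality,
        qc_report=qc_report,
        grs=grs,
        grs_summary=grs_summary,
        forest=forest,
        sensitivity_diff=sensitivity_diff,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


@_stage("report")
def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.main_table.to_csv(outdir / "main_associations.tsv", sep="\t", index=False)
    for trait, frame in result.per_snp.items():
        frame.to_csv(outdir / f"per_snp_{trait}.tsv", sep="\t", index=False)
    result.directionality.to_csv(outdir / "directionality.tsv", sep="\t", index=False)
    write_qc_report(result.qc_report, outdir / "qc_report.tsv")
    result.grs.to_csv(outdir / "grs.tsv", sep="\t", index=False)
    result.grs_summary.to_csv(outdir / "grs_summary.tsv", sep="\t")
    if not result.forest.empty:
        result.forest.to_csv(outdir / "forest_table.tsv", sep="\t", index=False)
        plot_forest(result.forest, outdir / "forest_homa_ir.png")
    if result.sensitivity_diff is not None:
        result.sensitivity_diff.to_csv(outdir / "sensitivity_diff.tsv", sep="\t", index=False)
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
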