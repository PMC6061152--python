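"""Additive-model association battery.

Conventions, matching the study design this package reproduces:

* every association is an ordinary least-squares fit of trait on predictor
  (GRS or single-variant dosage) under the additive genetic model, with
  optional age/sex/scanner adjustment;
* right-skewed traits are log10-transformed to meet the normality assumption,
  and the p-value from the transformed fit is reported, while effect size and
  SE are taken from the fit on the *untransformed* trait so they stay
  clinically interpretable;
* directional consistency of per-variant effects is assessed by an exact
  two-sided binomial test at p0 = 0.5 (minimum-likelihood two-sided
  definition, which at p0 = 0.5 equals doubling the tail);
* between-cohort effect-size differences use (b1 - b2)/sqrt(se1^2 + se2^2)
  against the standard normal (or Student t with Welch-Satterthwaite df);
* multiple testing within a cohort's trait battery is controlled by
  Benjamini-Hochberg FDR at q = 0.10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# configuration and result containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class TraitConfig:
    """Per-trait analysis settings.

    log_transform: report the p-value from the log10-transformed fit.
    covariates: subset of {age, sex, scanner}; scanner belongs only to
        DXA-derived traits.
    direction_expected: expected sign (+1/-1) of per-variant effects for the
        directionality test; 0 when no direction is hypothesised.
    """

    name: str
    log_transform: bool = False
    covariates: tuple[str, ...] = ()
    direction_expected: int = 0

    def __post_init__(self) -> None:
        bad = set(self.covariates) - {"age", "sex", "scanner"}
        if bad:
            raise ValueError(f"unknown covariates for {self.name}: {sorted(bad)}")
        if "scanner" in self.covariates and not self.name.startswith("fat_pct"):
            raise ValueError(f"scanner adjustment is reserved for DXA traits, not {self.name}")


#: Default 16-trait battery: log10 + age/sex for the skewed biochemical traits,
#: age/sex for HbA1c, WHR and DXA fat percentages (DXA also scanner-adjusted),
#: no adjustment for SD scores (already age/sex-standardised).
DEFAULT_TRAIT_BATTERY: tuple[TraitConfig, ...] = (
    TraitConfig("homa_ir", True, ("age", "sex"), +1),
    TraitConfig("fasting_insulin", True, ("age", "sex"), +1),
    TraitConfig("fasting_glucose", True, ("age", "sex")),
    TraitConfig("hba1c", False, ("age", "sex")),
    TraitConfig("ldl", True, ("age", "sex")),
    TraitConfig("hdl", True, ("age", "sex"), -1),
    TraitConfig("total_chol", True, ("age", "sex")),
    TraitConfig("triacylglycerol", True, ("age", "sex"), +1),
    TraitConfig("bmi_sds", False, ()),
    TraitConfig("whr", False, ("age", "sex")),
    TraitConfig("sbp_sds", False, ()),
    TraitConfig("dbp_sds", False, ()),
    TraitConfig("fat_pct_total", False, ("age", "sex", "scanner")),
    TraitConfig("fat_pct_torso", False, ("age", "sex", "scanner")),
    TraitConfig("fat_pct_legs", False, ("age", "sex", "scanner")),
    TraitConfig("fat_pct_arms", False, ("age", "sex", "scanner")),
)

#: Traits examined per variant (the insulin-resistance phenotype set).
PER_SNP_TRAITS: tuple[str, ...] = ("homa_ir", "fasting_insulin", "hdl", "triacylglycerol")


@dataclass
class AssociationResult:
    trait: str
    predictor: str
    beta: float
    se: float
    t_stat: float
    df: int
    p_raw: float
    p_log: Optional[float]
    n: int
    adjustments: tuple[str, ...]
    transform_flag: bool
    p_fdr: Optional[float] = None

    @property
    def p_report(self) -> float:
        """The p-value the battery reports: log10-fit p when flagged, else raw."""
        return self.p_log if (self.transform_flag and self.p_log is not None) else self.p_raw


@dataclass
class FitResult:
    betas: np.ndarray
    ses: np.ndarray
    t_stats: np.ndarray
    df: int
    p_values: np.ndarray
    rss: float = 0.0


# --------------------------------------------------------------------------- #
# core fits
# --------------------------------------------------------------------------- #

def fit_linear(y: np.ndarray, X: np.ndarray,
               column_names: Optional[Sequence[str]] = None) -> FitResult:
    """Ordinary least squares with classical (homoskedastic) standard errors.

    ``X`` must include the intercept column.  Two-sided p-values come from the
    Student t distribution with n - k degrees of freedom.  A rank-deficient
    design raises, naming the offending columns.  A perfect fit (zero residual
    sum of squares) yields zero SEs and NaN t/p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("y must be 1-d and X 2-d with matching rows")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("fit_linear requires complete cases (drop missing rows first)")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names = list(column_names) if column_names is not None else [f"x{j}" for j in range(k)]
        # columns whose removal restores full column rank are the collinear ones
        collinear = [
            names[j] for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design (rank {rank} < {k}); "
                         f"collinear columns: {collinear}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(ses > 0, beta / ses, np.nan)
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df)
    return FitResult(beta, ses, t_stats, df, p_values, rss)


def _design(
    frame: pd.DataFrame, predictor: str, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(frame)), frame[predictor].to_numpy(dtype=float)]
    names = ["intercept", predictor]
    for cov in covariates:
        if cov == "sex":
            col = (
                frame["sex"].map({"male": 0.0, "female": 1.0})
                if frame["sex"].dtype == object
                else frame["sex"].astype(float)
            )
            cols.append(col.to_numpy(dtype=float))
            names.append("sex")
        elif cov == "scanner":
            codes, levels = pd.factorize(frame["scanner_id"])
            if len(levels) > 1:  # a single scanner carries no information
                cols.append(codes.astype(float))
                names.append("scanner")
            else:
                logger.info("scanner adjustment skipped: single scanner level")
        else:
            cols.append(frame[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def _complete_cases(frame: pd.DataFrame, needed: Sequence[str]) -> pd.DataFrame:
    n0 = len(frame)
    out = frame.dropna(subset=[c for c in needed if c in frame.columns])
    dropped = n0 - len(out)
    if dropped:
        logger.info("dropped %d/%d incomplete cases for %s", dropped, n0, list(needed))
    return out


def _assoc(
    frame: pd.DataFrame,
    trait_cfg: TraitConfig,
    predictor_col: str,
    predictor_label: str,
) -> AssociationResult:
    needed = [trait_cfg.name, predictor_col] + [
        "scanner_id" if c == "scanner" else c for c in trait_cfg.covariates
    ]
    sub = _complete_cases(frame, needed)
    if sub.empty or sub[trait_cfg.name].isna().all():
        raise ValueError(f"trait {trait_cfg.name}: no complete cases")
    y = sub[trait_cfg.name].to_numpy(dtype=float)
    X, names = _design(sub, predictor_col, trait_cfg.covariates)
    names[1] = predictor_label
    fit = fit_linear(y, X, names)

    p_log = None
    if trait_cfg.log_transform:
        nonpos = sub.index[y <= 0]
        if len(nonpos):
            raise ValueError(
                f"trait {trait_cfg.name}: log10 transform requested but "
                f"non-positive values at rows {list(nonpos)[:10]}"
            )
        fit_log = fit_linear(np.log10(y), X, names)
        p_log = float(fit_log.p_values[1])

    return AssociationResult(
        trait=trait_cfg.name,
        predictor=predictor_label,
        beta=float(fit.betas[1]),
        se=float(fit.ses[1]),
        t_stat=float(fit.t_stats[1]),
        df=fit.df,
        p_raw=float(fit.p_values[1]),
        p_log=p_log,
        n=len(sub),
        adjustments=trait_cfg.covariates,
        transform_flag=trait_cfg.log_transform,
    )


def assoc_grs(
    pheno: pd.DataFrame,
    grs: pd.DataFrame,
    trait_cfg: TraitConfig,
    grs_col: str = "grs_unweighted",
    drop_excluded: bool = False,
) -> AssociationResult:
    """Regress one trait on the genetic risk score with the trait's adjustments.

    Effect size and SE come from the untransformed-trait fit; when
    ``trait_cfg.log_transform`` is set the log10-trait fit (same case set,
    same design) supplies ``p_log``.  ``drop_excluded`` removes rows whose
    ``exclusion_flag`` is set (sensitivity analysis).
    """
    frame = pheno.merge(grs[["sample_id", grs_col]], on="sample_id", how="inner")
    if drop_excluded and "exclusion_flag" in frame.columns:
        n0 = len(frame)
        frame = frame[~frame["exclusion_flag"].astype(bool)]
        logger.info("sensitivity mode: excluded %d flagged participants", n0 - len(frame))
    return _assoc(frame, trait_cfg, grs_col, grs_col)


def per_snp_assoc(
    matrix: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait_cfg: TraitConfig,
    drop_excluded: bool = False,
) -> list[AssociationResult]:
    """Per-variant additive-model fits for one trait, in panel order.

    Variants with zero dosage variance among complete cases are skipped with
    a warning (their effect is not identifiable).
    """
    pheno_idx = pheno.set_index("sample_id")
    if drop_excluded and "exclusion_flag" in pheno_idx.columns:
        pheno_idx = pheno_idx[~pheno_idx["exclusion_flag"].astype(bool)]
    results: list[AssociationResult] = []
    for j, v in enumerate(matrix.variants):
        dose = pd.Series(matrix.column(j), index=matrix.sample_ids, name="_dosage")
        frame = pheno_idx.join(dose, how="inner").reset_index(names="sample_id")
        sub = frame.dropna(subset=["_dosage", trait_cfg.name])
        if sub.empty or np.nanstd(sub["_dosage"].to_numpy(dtype=float)) == 0.0:
            logger.warning("variant %s skipped for %s: zero dosage variance",
                           v.variant_id, trait_cfg.name)
            continue
        res = _assoc(frame, trait_cfg, "_dosage", v.variant_id)
        results.append(res)
    return results


# --------------------------------------------------------------------------- #
# derived tests
# --------------------------------------------------------------------------- #

def direction_binomial(
    signs: Sequence[int], expected: Sequence[int] | int
) -> tuple[int, int, float]:
    """Exact two-sided binomial test of directional consistency.

    ``signs`` are the signs of per-variant effect estimates; ``expected`` the
    hypothesised signs (scalar or per-variant).  Returns (number consistent,
    number tested, two-sided p at p0 = 0.5) using the minimum-likelihood
    two-sided definition (sum of outcome probabilities not exceeding that of
    the observed count), which at p0 = 0.5 equals the doubled tail, capped
    at 1.
    """
    signs_arr = np.asarray(signs, dtype=int)
    if signs_arr.size == 0:
        raise ValueError("no effect signs supplied")
    exp_arr = np.broadcast_to(np.asarray(expected, dtype=int), signs_arr.shape)
    if np.any(signs_arr == 0) or np.any(exp_arr == 0):
        raise ValueError("signs and expected directions must be +1 or -1")
    k = int((signs_arr == exp_arr).sum())
    n = int(signs_arr.size)
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return k, n, p


def heterogeneity_test(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    df_mode: Literal["normal", "welch"] = "normal",
    n1: Optional[int] = None,
    n2: Optional[int] = None,
) -> tuple[float, float]:
    """Two-sample effect-size comparison from summary statistics.

    statistic = (b1 - b2) / sqrt(se1^2 + se2^2); two-sided p from the standard
    normal (default) or, with ``df_mode='welch'`` and both group sizes given,
    from Student t with Welch-Satterthwaite degrees of freedom.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    stat = (beta1 - beta2) / np.hypot(se1, se2)
    if df_mode == "normal":
        p = 2.0 * stats.norm.sf(abs(stat))
    elif df_mode == "welch":
        if n1 is None or n2 is None:
            raise ValueError("df_mode='welch' requires n1 and n2")
        v1, v2 = se1**2, se2**2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(stat), df)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    return float(stat), float(p)


def bh_fdr(p_values: Sequence[float], q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def attach_fdr(results: Iterable[AssociationResult], q: float = 0.10) -> list[AssociationResult]:
    """Set ``p_fdr`` across one family of results (one cohort's battery)."""
    results = list(results)
    p_adj, _ = bh_fdr([r.p_report for r in results], q)
    for r, adj in zip(results, p_adj):
        r.p_fdr = float(adj)
    return results


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "trait": r.trait,
                "predictor": r.predictor,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_log": r.p_log,
                "p_report": r.p_report,
                "p_fdr": r.p_fdr,
                "log_transformed": r.transform_flag,
                "adjustments": "+".join(r.adjustments) if r.adjustments else "none",
            }
        )
    return pd.DataFrame(rows)
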