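"""Variant-level quality control: call rate, Hardy–Weinberg, imputation quality.

The Hardy–Weinberg test is the exact conditional (Levene–Haldane) test:
conditioning on the observed allele counts, the heterozygote count h follows

    P(h | n, n_minor) = C * n! 2^h / (n_AA! h! n_aa!),

and the two-sided p-value sums the probabilities of all configurations no
more probable than the observed one.  A chi-square (1 df) variant is offered
for users who want the asymptotic test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

# relative slack when comparing configuration probabilities (float round-off)
_REL_TOL = 1e-12


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value from genotype counts.

    Parameters are counts of reference homozygotes, heterozygotes and
    alternate homozygotes.  Monomorphic variants return 1.0 (only one
    configuration is possible given the allele counts).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    if any(c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be integers: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0

    n_minor = min(n_a, n_b)
    # valid heterozygote counts share the parity of the minor allele count
    h = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_a = (n_a - h) // 2
    hom_b = (n_b - h) // 2
    log_unnorm = h * np.log(2.0) - gammaln(hom_a + 1) - gammaln(h + 1) - gammaln(hom_b + 1)
    log_unnorm -= log_unnorm.max()
    prob = np.exp(log_unnorm)
    prob /= prob.sum()
    p_obs = prob[h == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + _REL_TOL)].sum()))


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Asymptotic 1-df chi-square Hardy–Weinberg test (no continuity correction)."""
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array(counts, dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


@dataclass
class QCParams:
    """Variant-filter thresholds.

    hwe_alpha: variants with exact HWE p <= alpha are removed (retained
        requires p > alpha).
    min_call_rate: minimum fraction of non-missing dosages.
    min_info: minimum imputation-quality R^2; only applied when info scores
        are supplied (retained requires info > min_info).
    hardcall_threshold: dosages within this distance of {0, 1, 2} are rounded
        to hard genotype calls for the HWE test; others are treated as missing
        for HWE only.
    min_hardcall_fraction: below this fraction of hard-callable samples the
        HWE test is recorded as not computable.
    keep_hwe_uncomputable: retain variants whose HWE p could not be computed
        (mirrors testing HWE on directly genotyped variants, before
        imputation-style dosage smearing).
    hwe_method: 'exact' (Levene–Haldane) or 'chisq'.
    """

    hwe_alpha: float = 0.05
    min_call_rate: float = 0.95
    min_info: float = 0.95
    hardcall_threshold: float = 0.1
    min_hardcall_fraction: float = 0.9
    keep_hwe_uncomputable: bool = True
    hwe_method: Literal["exact", "chisq"] = "exact"

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "min_call_rate", "min_info",
                     "hardcall_threshold", "min_hardcall_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_method {self.hwe_method!r}")


def hardcalls(dosage: np.ndarray, missing: np.ndarray, threshold: float) -> np.ndarray:
    """Round dosages to {0, 1, 2} where within ``threshold``; NaN elsewhere."""
    rounded = np.round(dosage)
    ok = (np.abs(dosage - rounded) <= threshold) & ~missing & (rounded >= 0) & (rounded <= 2)
    out = np.where(ok, rounded, np.nan)
    return out


def genotype_counts(hard: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_ref, n_het, n_hom_alt) from a hard-call vector (NaN = missing).

    'ref' here means zero copies of the counted allele.
    """
    obs = hard[np.isfinite(hard)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_variants(
    matrix: GenotypeMatrix,
    params: Optional[QCParams] = None,
    info_scores: Optional[Sequence[float]] = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply variant-level QC; return the filtered matrix and a QC report.

    The report has one row per input variant with its call rate, HWE p-value
    (NaN when not computable on hard calls), optional imputation R^2, the pass
    flag and the failure reasons.  Surviving dosage values are returned
    unchanged.
    """
    params = params or QCParams()
    n, m = matrix.dosage.shape
    if info_scores is not None and len(info_scores) != m:
        raise ValueError("info_scores length does not match variant count")

    hwe_fn = hwe_exact_test if params.hwe_method == "exact" else hwe_chisq_test
    rows = []
    keep: list[int] = []
    call_rates = matrix.call_rates()
    for j, v in enumerate(matrix.variants):
        reasons: list[str] = []
        cr = float(call_rates[j])
        if cr < params.min_call_rate:
            reasons.append("call_rate")

        hard = hardcalls(matrix.dosage[:, j], matrix.missing[:, j], params.hardcall_threshold)
        n_obs = (~matrix.missing[:, j]).sum()
        hwe_p = np.nan
        if n_obs > 0 and np.isfinite(hard).sum() >= params.min_hardcall_fraction * n_obs \
                and np.isfinite(hard).any():
            hwe_p = hwe_fn(*genotype_counts(hard))
            if hwe_p <= params.hwe_alpha:
                reasons.append("HWE")
        elif not params.keep_hwe_uncomputable:
            reasons.append("HWE_not_computable")

        info = np.nan
        if info_scores is not None:
            info = float(info_scores[j])
            if not np.isnan(info) and info <= params.min_info:
                reasons.append("info")

        passed = not reasons
        rows.append(
            {
                "variant_id": v.variant_id,
                "call_rate": cr,
                "hwe_p": hwe_p,
                "info_r2": info,
                "pass": passed,
                "reasons": ";".join(reasons),
            }
        )
        if passed:
            keep.append(j)
        else:
            logger.info("variant %s removed (%s)", v.variant_id, ";".join(reasons))

    report = pd.DataFrame(rows)
    logger.info("variant QC: %d/%d variants retained", len(keep), m)
    return matrix.select_variants(keep), report


def write_qc_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
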