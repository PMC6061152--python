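"""Genetic risk score construction from effect-allele dosages.

Two scores are computed per individual over a fixed J-variant panel:

* unweighted: the sum of effect-allele dosages, GRS_i = sum_j d_ij (0..2J);
* weighted: dosages weighted by per-allele effect sizes and normalised by the
  sum of the effects, by default rescaled back to the 0..2J allele-count
  scale, GRS_i = J * (sum_j w_j d_ij) / (sum_j w_j), so that the two scores
  are directly comparable (equal weights make them identical).

Missing dosages are handled by proportional rescaling of the observed panel
fraction (default), by frequency imputation from the sample, or strictly
(any missing variant voids the score).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .panel import WeightTable

MissingPolicy = Literal["rescale", "mean-impute", "strict"]
Normalization = Literal["count-scale", "unit-scale"]


def _observed(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.n_variants == 0:
        raise ValueError("empty panel: no variants to score")
    obs = ~matrix.missing
    d = np.where(obs, matrix.dosage, 0.0)
    return d, obs


def _mean_impute(d: np.ndarray, obs: np.ndarray) -> np.ndarray:
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        cols = np.where(n_obs == 0)[0]
        raise ValueError(f"cannot frequency-impute all-missing variant columns {cols.tolist()}")
    col_mean = d.sum(axis=0) / n_obs
    return np.where(obs, d, col_mean)


def unweighted_grs(
    matrix: GenotypeMatrix,
    missing_policy: MissingPolicy = "rescale",
    min_fraction: float = 0.9,
) -> pd.Series:
    """Allele-count score per sample; NaN where too few variants are observed."""
    d, obs = _observed(matrix)
    J = matrix.n_variants
    j_obs = obs.sum(axis=1)

    if missing_policy == "rescale":
        with np.errstate(invalid="ignore", divide="ignore"):
            score = d.sum(axis=1) * (J / j_obs)
    elif missing_policy == "mean-impute":
        score = _mean_impute(d, obs).sum(axis=1)
    elif missing_policy == "strict":
        score = np.where(j_obs == J, d.sum(axis=1), np.nan)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    score = np.where(j_obs >= min_fraction * J, score, np.nan)
    score = np.where(j_obs == 0, np.nan, score)
    return pd.Series(score, index=pd.Index(matrix.sample_ids, name="sample_id"),
                     name="grs_unweighted")


def weighted_grs(
    matrix: GenotypeMatrix,
    panel: WeightTable,
    missing_policy: MissingPolicy = "rescale",
    min_fraction: float = 0.9,
    normalization: Normalization = "count-scale",
) -> pd.Series:
    """Effect-size-weighted score per sample.

    Weights must be strictly positive: the panel is oriented so every effect
    allele is risk-increasing, and its weight is the (positive) magnitude of
    the per-allele effect.  With ``count-scale`` (default) the score lives on
    the 0..2J allele-count scale; ``unit-scale`` keeps the literal
    sum(w*d)/sum(w) in [0, 2].
    """
    w = panel.weights
    if len(w) != matrix.n_variants:
        raise ValueError("panel size does not match genotype matrix")
    if (w <= 0).any():
        bad = [panel[j].variant_id for j in np.where(w <= 0)[0]]
        raise ValueError(f"non-positive weights (panel must be risk-oriented): {bad}")
    d, obs = _observed(matrix)
    J = matrix.n_variants
    j_obs = obs.sum(axis=1)
    scale = float(J) if normalization == "count-scale" else 1.0
    if normalization not in ("count-scale", "unit-scale"):
        raise ValueError(f"unknown normalization {normalization!r}")

    if missing_policy == "rescale":
        w_obs = (obs * w).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = scale * (d * w).sum(axis=1) / w_obs
    elif missing_policy == "mean-impute":
        score = scale * (_mean_impute(d, obs) * w).sum(axis=1) / w.sum()
    elif missing_policy == "strict":
        score = np.where(j_obs == J, scale * (d * w).sum(axis=1) / w.sum(), np.nan)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    score = np.where(j_obs >= min_fraction * J, score, np.nan)
    score = np.where(j_obs == 0, np.nan, score)
    return pd.Series(score, index=pd.Index(matrix.sample_ids, name="sample_id"),
                     name="grs_weighted")


def compute_grs(
    matrix: GenotypeMatrix,
    panel: Optional[WeightTable] = None,
    missing_policy: MissingPolicy = "rescale",
    min_fraction: float = 0.9,
    normalization: Normalization = "count-scale",
) -> pd.DataFrame:
    """Both scores plus the per-sample count of observed variants, as a table."""
    out = unweighted_grs(matrix, missing_policy, min_fraction).to_frame()
    if panel is not None:
        out["grs_weighted"] = weighted_grs(matrix, panel, missing_policy,
                                           min_fraction, normalization)
    out["n_variants_used"] = (~matrix.missing).sum(axis=1)
    return out.reset_index()
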