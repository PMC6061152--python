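"""Derived clinical indices: HOMA-IR, Friedewald LDL, LMS-based SD scores, BP, WHR.

Units follow common European clinical practice: glucose and lipids in mmol/l,
insulin in pmol/l, blood pressure in mmHg, waist/hip in cm.  With insulin in
pmol/l the HOMA-IR denominator is 135 (it would be 22.5 for uU/ml).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ArrayLike = Union[float, np.ndarray, pd.Series]

HOMA_IR_DENOMINATOR = 135.0  # insulin in pmol/l
FRIEDEWALD_TG_LIMIT = 4.5  # mmol/l; above this the formula is invalid
LMS_L_EPS = 1e-7  # |L| below this uses the log-limit form

# plausible fasting-insulin range in pmol/l; values far below suggest uU/ml input
INSULIN_PMOL_WARN_BELOW = 3.0


def _check_nonneg(name: str, value: ArrayLike) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def homa_ir(glucose_mmol: ArrayLike, insulin_pmol: ArrayLike) -> ArrayLike:
    """Homeostasis model assessment of insulin resistance.

    HOMA-IR = glucose [mmol/l] x insulin [pmol/l] / 135.
    """
    g = _check_nonneg("glucose", glucose_mmol)
    i = _check_nonneg("insulin", insulin_pmol)
    finite = i[np.isfinite(i)]
    if finite.size and np.nanmedian(finite) < INSULIN_PMOL_WARN_BELOW:
        warnings.warn(
            "median fasting insulin < 3 pmol/l; input may be in uU/ml "
            "(HOMA-IR here expects pmol/l)",
            stacklevel=2,
        )
    out = g * i / HOMA_IR_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(
    total_chol: ArrayLike, hdl: ArrayLike, tg: ArrayLike, tg_limit: float = FRIEDEWALD_TG_LIMIT
) -> ArrayLike:
    """LDL cholesterol by the Friedewald formula (all mmol/l).

    LDL = total - HDL - TG/5.  Invalid (returned as NaN, with a warning) when
    triacylglycerol exceeds ``tg_limit`` (default 4.5 mmol/l), where the
    fixed TG:VLDL ratio underlying the formula breaks down.
    """
    tc = _check_nonneg("total cholesterol", total_chol)
    h = _check_nonneg("HDL", hdl)
    t = _check_nonneg("triacylglycerol", tg)
    ldl = tc - h - t / 5.0
    over = t > tg_limit
    if np.any(over):
        warnings.warn(
            f"{int(np.sum(over))} sample(s) with triacylglycerol > {tg_limit} mmol/l: "
            "Friedewald LDL set to missing",
            stacklevel=2,
        )
        ldl = np.where(over, np.nan, ldl)
    return float(ldl) if np.ndim(ldl) == 0 else ldl


def lms_sds(x: ArrayLike, L: ArrayLike, M: ArrayLike, S: ArrayLike) -> ArrayLike:
    """SD score via the LMS (lambda-mu-sigma) transform.

    z = ((x/M)^L - 1) / (L*S) for |L| > eps, and z = ln(x/M)/S in the L -> 0
    limit.  L is the Box-Cox skewness power, M the reference median, S the
    coefficient of variation at the given age/sex.
    """
    x_, L_, M_, S_ = (np.asarray(a, dtype=float) for a in (x, L, M, S))
    if np.any(x_[np.isfinite(x_)] <= 0):
        raise ValueError("x must be positive")
    if np.any(M_[np.isfinite(M_)] <= 0) or np.any(S_[np.isfinite(S_)] <= 0):
        raise ValueError("M and S must be positive")
    ratio = x_ / M_
    with np.errstate(invalid="ignore"):
        z = np.where(
            np.abs(L_) > LMS_L_EPS,
            (np.power(ratio, L_) - 1.0) / (L_ * S_),
            np.log(ratio) / S_,
        )
    return float(z) if np.ndim(z) == 0 else z


def inverse_lms(z: ArrayLike, L: ArrayLike, M: ArrayLike, S: ArrayLike) -> ArrayLike:
    """Measurement value at SD score ``z``: x = M (1 + L S z)^(1/L), M e^(Sz) as L -> 0."""
    z_, L_, M_, S_ = (np.asarray(a, dtype=float) for a in (z, L, M, S))
    with np.errstate(invalid="ignore"):
        x = np.where(
            np.abs(L_) > LMS_L_EPS,
            M_ * np.power(1.0 + L_ * S_ * z_, 1.0 / np.where(np.abs(L_) > LMS_L_EPS, L_, 1.0)),
            M_ * np.exp(S_ * z_),
        )
    return float(x) if np.ndim(x) == 0 else x


@dataclass
class LMSReference:
    """A sex x age grid of (L, M, S) parameters for SD-score computation.

    Loaded from a CSV with columns ``sex, age_years, L, M, S`` (sex coded
    ``male``/``female``).  Parameters are linearly interpolated in age; ages
    outside the grid raise (no extrapolation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS reference lacks columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("LMS reference M and S must be positive")
        self._grids = {}
        for sex, grp in self.table.groupby("sex"):
            grp = grp.sort_values("age_years")
            ages = grp["age_years"].to_numpy(dtype=float)
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise ValueError(f"LMS grid for sex={sex!r} must be strictly increasing in age")
            self._grids[sex] = (ages, grp[["L", "M", "S"]].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, age: ArrayLike, sex: ArrayLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(L, M, S) interpolated at each (age, sex)."""
        age_ = np.atleast_1d(np.asarray(age, dtype=float))
        sex_ = np.atleast_1d(np.asarray(sex, dtype=object))
        if sex_.size == 1 and age_.size > 1:
            sex_ = np.repeat(sex_, age_.size)
        out = np.empty((age_.size, 3))
        for s in np.unique(sex_):
            if s not in self._grids:
                raise ValueError(f"sex {s!r} not in LMS reference (has {list(self._grids)})")
            ages, lms = self._grids[s]
            idx = sex_ == s
            a = age_[idx]
            if np.any(a < ages[0]) or np.any(a > ages[-1]):
                raise ValueError(
                    f"age outside LMS reference span [{ages[0]}, {ages[-1]}] for sex {s!r}"
                )
            for k in range(3):
                out[idx, k] = np.interp(a, ages, lms[:, k])
        return out[:, 0], out[:, 1], out[:, 2]

    def sds(self, value: ArrayLike, age: ArrayLike, sex: ArrayLike) -> ArrayLike:
        """SD score of ``value`` against the reference at (age, sex)."""
        L, M, S = self.lookup(age, sex)
        z = lms_sds(np.atleast_1d(np.asarray(value, dtype=float)), L, M, S)
        return float(z[0]) if np.ndim(value) == 0 else z


def sds_from_reference(
    value: ArrayLike, age: ArrayLike, sex: ArrayLike, ref: LMSReference
) -> ArrayLike:
    """Functional wrapper around :meth:`LMSReference.sds`."""
    return ref.sds(value, age, sex)


def average_bp(readings: Sequence[float]) -> tuple[float, bool]:
    """Blood pressure summary: mean of the last two of up to three readings.

    Returns ``(value, single_reading_flag)``; with a single reading that
    reading is returned and flagged.
    """
    vals = [float(r) for r in readings if r is not None and np.isfinite(r)]
    if not vals:
        raise ValueError("no blood pressure readings")
    if len(vals) > 3:
        raise ValueError("more than three blood pressure readings")
    if len(vals) == 1:
        return vals[0], True
    return float(np.mean(vals[-2:])), False


def whr(waist_cm: ArrayLike, hip_cm: ArrayLike) -> ArrayLike:
    """Waist-to-hip ratio: waist [cm] / hip [cm]."""
    w = _check_nonneg("waist", waist_cm)
    h = np.asarray(hip_cm, dtype=float)
    if np.any(h[np.isfinite(h)] <= 0):
        raise ValueError("hip circumference must be positive")
    out = w / h
    return float(out) if out.ndim == 0 else out


def derive_phenotypes(
    pheno: pd.DataFrame,
    bmi_reference: Optional[LMSReference] = None,
    sbp_reference: Optional[LMSReference] = None,
    dbp_reference: Optional[LMSReference] = None,
) -> pd.DataFrame:
    """Append derived columns to a raw phenotype table.

    Adds ``homa_ir``, ``ldl`` (Friedewald), ``whr``; averages BP reading
    columns (``sbp_1..3`` / ``dbp_1..3``) into ``sbp``/``dbp``; and, when the
    corresponding LMS references are given, ``bmi_sds``, ``sbp_sds`` and
    ``dbp_sds`` (sex/age-standardised).  Existing columns are preserved.
    """
    out = pheno.copy()
    if {"fasting_glucose", "fasting_insulin"} <= set(out.columns):
        out["homa_ir"] = homa_ir(out["fasting_glucose"], out["fasting_insulin"])
    if {"total_chol", "hdl", "triacylglycerol"} <= set(out.columns):
        out["ldl"] = friedewald_ldl(out["total_chol"], out["hdl"], out["triacylglycerol"])
    if {"waist", "hip"} <= set(out.columns):
        out["whr"] = whr(out["waist"], out["hip"])

    for prefix in ("sbp", "dbp"):
        cols = [c for c in (f"{prefix}_1", f"{prefix}_2", f"{prefix}_3") if c in out.columns]
        if cols:
            readings = out[cols].to_numpy(dtype=float)
            means = np.full(len(out), np.nan)
            flags = np.zeros(len(out), dtype=bool)
            for i in range(len(out)):
                row = readings[i][np.isfinite(readings[i])]
                if row.size:
                    means[i], flags[i] = average_bp(row.tolist())
            out[prefix] = means
            out[f"{prefix}_single_reading"] = flags

    def _sds_col(src: str, ref: Optional[LMSReference], dest: str) -> None:
        if ref is None or src not in out.columns:
            return
        vals = out[src].to_numpy(dtype=float)
        z = np.full(len(out), np.nan)
        ok = np.isfinite(vals) & out["age"].notna() & out["sex"].notna()
        if ok.any():
            z[ok] = ref.sds(vals[ok], out.loc[ok, "age"].to_numpy(dtype=float),
                            out.loc[ok, "sex"].to_numpy(dtype=object))
        out[dest] = z

    _sds_col("bmi", bmi_reference, "bmi_sds")
    _sds_col("sbp", sbp_reference, "sbp_sds")
    _sds_col("dbp", dbp_reference, "dbp_sds")
    return out
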