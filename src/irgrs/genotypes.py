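"""Genotype input and effect-allele alignment.

Genotypes arrive either as a VCF (per-sample ``DS`` dosage field, or hard
``GT`` calls) or as a plain TSV dosage matrix (samples x variants).  They are
projected onto a :class:`~irgrs.panel.WeightTable` and the dosages re-oriented
so that every column counts the panel's effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import VariantRecord, WeightTable

logger = logging.getLogger(__name__)

AmbiguousPolicy = Literal["trust", "drop", "error"]


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosages in [0, 2] with a missingness mask.

    ``counted_allele[j]`` records which allele column ``j`` currently counts;
    after :func:`align_to_effect_allele` it equals the panel's effect allele.
    ``uncounted_allele[j]`` is the other allele seen in the source file (None
    when the source carries no allele labels, e.g. a bare TSV matrix).
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # float, shape (n_samples, n_variants)
    missing: np.ndarray  # bool, same shape
    counted_allele: list[str] = field(default_factory=list)
    uncounted_allele: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variants length does not match dosage columns")
        if self.missing.shape != self.dosage.shape:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not self.counted_allele:
            self.counted_allele = [v.effect_allele for v in self.variants]
        if not self.uncounted_allele:
            self.uncounted_allele = [v.other_allele for v in self.variants]
        obs = self.dosage[~self.missing]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 2):
            i, j = np.argwhere(~self.missing & ((self.dosage < 0) | (self.dosage > 2)))[0]
            raise ValueError(
                f"dosage outside [0, 2] at sample {self.sample_ids[i]!r}, "
                f"variant {self.variants[j].variant_id!r}: {self.dosage[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def call_rates(self) -> np.ndarray:
        """Per-variant fraction of non-missing dosages."""
        return 1.0 - self.missing.mean(axis=0)

    def column(self, j: int) -> np.ndarray:
        """Dosages for variant ``j`` with missing entries as NaN."""
        d = self.dosage[:, j].astype(float).copy()
        d[self.missing[:, j]] = np.nan
        return d

    def select_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
            missing=self.missing[:, keep].copy(),
            counted_allele=[self.counted_allele[j] for j in keep],
            uncounted_allele=[self.uncounted_allele[j] for j in keep],
        )

    def to_tsv(self, path: str | Path, precision: int = 4) -> None:
        """Write the dosage matrix TSV (header = variant ids, empty cell = missing)."""
        df = pd.DataFrame(
            np.round(self.dosage, precision),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[v.variant_id for v in self.variants],
        )
        df = df.mask(self.missing)
        df.to_csv(path, sep="\t", float_format=f"%.{precision}f")


def read_genotypes(
    path: str | Path,
    panel: WeightTable,
    format_hint: Optional[Literal["vcf", "tsv"]] = None,
) -> GenotypeMatrix:
    """Read genotypes for the panel variants, in panel order.

    VCF files are matched by rsID first and by chrom:pos as a fallback; a bare
    TSV dosage matrix is matched by column header.  Panel variants absent from
    the file become all-missing columns (logged).  The returned matrix counts
    the file's counted allele (ALT for a VCF); call
    :func:`align_to_effect_allele` before scoring.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} or ".vcf" in path.suffixes else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, panel)
    return _read_tsv(path, panel)


def _read_vcf(path: Path, panel: WeightTable) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids in {path}")
    n = len(samples)
    m = len(panel)
    by_id = panel.by_id()
    by_pos = panel.by_position()
    col_index = {v.variant_id: j for j, v in enumerate(panel)}

    dosage = np.zeros((n, m))
    missing = np.ones((n, m), dtype=bool)
    counted: list[str] = [v.effect_allele for v in panel]
    uncounted: list[Optional[str]] = [v.other_allele for v in panel]
    seen: set[str] = set()

    for var in vcf:
        rec = by_id.get(var.ID) if var.ID else None
        if rec is None:
            rec = by_pos.get(f"{var.CHROM}:{var.POS}")
        if rec is None:
            continue
        j = col_index[rec.variant_id]
        if rec.variant_id in seen:
            raise ValueError(f"variant {rec.variant_id} appears more than once in {path}")
        seen.add(rec.variant_id)
        if len(var.ALT) != 1:
            raise ValueError(f"variant {rec.variant_id}: multiallelic records are not supported")
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(col) | (col < -0.5)
        else:
            # gts012: 0/1/2 = ALT allele count, 3 = missing
            col = var.gt_types.astype(float)
            miss = col == 3
            col[miss] = 0.0
        bad = ~miss & ((col < 0) | (col > 2))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"dosage outside [0, 2] at sample {samples[i]!r}, "
                f"variant {rec.variant_id!r}: {col[i]}"
            )
        col[miss] = 0.0
        dosage[:, j] = col
        missing[:, j] = miss
        counted[j] = var.ALT[0]  # DS and GT count ALT alleles
        uncounted[j] = var.REF

    absent = [v.variant_id for v in panel if v.variant_id not in seen]
    if absent:
        logger.info("panel variants absent from %s (all-missing): %s", path, absent)

    return GenotypeMatrix(
        sample_ids=samples,
        variants=list(panel.variants),
        dosage=dosage,
        missing=missing,
        counted_allele=counted,
        uncounted_allele=uncounted,
    )


def _read_tsv(path: Path, panel: WeightTable) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids in {path}")
    n, m = len(samples), len(panel)
    dosage = np.zeros((n, m))
    missing = np.ones((n, m), dtype=bool)
    absent = []
    for j, v in enumerate(panel):
        if v.variant_id not in df.columns:
            absent.append(v.variant_id)
            continue
        col = pd.to_numeric(df[v.variant_id], errors="coerce").to_numpy(dtype=float)
        miss = ~np.isfinite(col)
        bad = ~miss & ((col < 0) | (col > 2))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"dosage outside [0, 2] at sample {samples[i]!r}, "
                f"variant {v.variant_id!r}: {col[i]}"
            )
        col[miss] = 0.0
        dosage[:, j] = col
        missing[:, j] = miss
    if absent:
        logger.info("panel variants absent from %s (all-missing): %s", path, absent)
    # a bare dosage matrix carries no allele labels; assume effect-allele counts
    return GenotypeMatrix(
        sample_ids=samples,
        variants=list(panel.variants),
        dosage=dosage,
        missing=missing,
        counted_allele=[v.effect_allele for v in panel],
        uncounted_allele=[None] * m,
    )


def align_to_effect_allele(
    matrix: GenotypeMatrix,
    panel: WeightTable,
    ambiguous_policy: AmbiguousPolicy = "trust",
) -> GenotypeMatrix:
    """Re-orient dosages so every column counts the panel's effect allele.

    A column whose counted allele equals the panel's *other* allele is flipped
    (d -> 2 - d).  Palindromic A/T and C/G variants, whose orientation is not
    resolvable from allele labels alone, are handled per ``ambiguous_policy``:
    ``trust`` keeps them as-is with a warning, ``drop`` blanks the column,
    ``error`` raises.  Applying the function twice is a no-op.
    """
    if ambiguous_policy not in ("trust", "drop", "error"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    by_id = panel.by_id()
    dosage = matrix.dosage.copy()
    missing = matrix.missing.copy()
    counted = list(matrix.counted_allele)
    uncounted = list(matrix.uncounted_allele)

    for j, v in enumerate(matrix.variants):
        rec = by_id.get(v.variant_id)
        if rec is None:
            raise ValueError(f"variant {v.variant_id} not in panel")
        if rec.is_palindromic:
            if ambiguous_policy == "error":
                raise ValueError(
                    f"palindromic variant {rec.variant_id} "
                    f"({rec.effect_allele}/{rec.other_allele}) with policy 'error'"
                )
            if ambiguous_policy == "drop":
                logger.warning("dropping palindromic variant %s", rec.variant_id)
                missing[:, j] = True
                continue
            logger.warning(
                "palindromic variant %s kept as-is (strand not verifiable)", rec.variant_id
            )
        cnt = counted[j]
        if cnt == rec.effect_allele:
            continue
        if cnt == rec.other_allele:
            obs = ~missing[:, j]
            dosage[obs, j] = 2.0 - dosage[obs, j]
            counted[j] = rec.effect_allele
            uncounted[j] = rec.other_allele
        else:
            raise ValueError(
                f"variant {rec.variant_id}: file alleles ({cnt}/{uncounted[j]}) "
                f"match neither panel allele ({rec.effect_allele}/{rec.other_allele})"
            )

    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variants=list(matrix.variants),
        dosage=dosage,
        missing=missing,
        counted_allele=counted,
        uncounted_allele=uncounted,
    )
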