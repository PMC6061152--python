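"""SNP weight panel: the fixed set of risk variants a genetic risk score is built from.

A panel row names a variant, the *effect allele* whose dosage the score and
all downstream regressions count (here: the insulin-resistance-increasing
allele), the other allele, and a per-allele weight (effect on fasting insulin
adjusted for BMI, log-scale units from the source GWAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class VariantRecord:
    """One panel variant with its effect-allele orientation and weight."""

    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    effect_allele: str
    other_allele: str
    weight: float
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: weight is not finite")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be 1-based (got {self.pos})")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand cannot be resolved from alleles."""
        return {self.effect_allele, self.other_allele} in PALINDROMIC_PAIRS

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class WeightTable:
    """An ordered panel of :class:`VariantRecord`, loadable from a TSV.

    The TSV dialect has a header with columns ``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``weight`` and optionally
    ``gene`` (nearest-gene label used in forest-style reports).
    """

    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.variants)

    def __getitem__(self, i: int) -> VariantRecord:
        return self.variants[i]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    def by_id(self) -> dict[str, VariantRecord]:
        return {v.variant_id: v for v in self.variants}

    def by_position(self) -> dict[str, VariantRecord]:
        pos_map: dict[str, VariantRecord] = {}
        for v in self.variants:
            if v.key in pos_map:
                raise ValueError(f"panel position collision at {v.key}")
            pos_map[v.key] = v
        return pos_map

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weights table {path} lacks columns: {sorted(missing)}")
        has_gene = "gene" in df.columns
        variants = [
            VariantRecord(
                variant_id=str(r.variant_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=str(r.effect_allele),
                other_allele=str(r.other_allele),
                weight=float(r.weight),
                gene=str(r.gene) if has_gene and not pd.isna(r.gene) else None,
            )
            for r in df.itertuples(index=False)
        ]
        return cls(variants)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "weight": [v.weight for v in self.variants],
                "gene": [v.gene for v in self.variants],
            }
        )

    def subset(self, variant_ids: Sequence[str]) -> "WeightTable":
        keep = set(variant_ids)
        return WeightTable([v for v in self.variants if v.variant_id in keep])
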