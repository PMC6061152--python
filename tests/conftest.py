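import numpy as np
import pytest

from irgrs.genotypes import GenotypeMatrix
from irgrs.panel import VariantRecord, WeightTable


@pytest.fixture
def rng():
    return np.random.default_rng(20180531)


@pytest.fixture
def small_panel():
    return WeightTable(
        [
            VariantRecord("rs1", "1", 100, "A", "G", 0.01, gene="G1"),
            VariantRecord("rs2", "2", 200, "C", "T", 0.03, gene="G2"),
            VariantRecord("rs3", "3", 300, "G", "A", 0.02, gene="G3"),
        ]
    )


def make_matrix(panel, dosage, missing=None, counted=None):
    dosage = np.asarray(dosage, dtype=float)
    if missing is None:
        missing = np.zeros_like(dosage, dtype=bool)
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(dosage.shape[0])],
        variants=list(panel.variants),
        dosage=dosage,
        missing=np.asarray(missing, dtype=bool),
        counted_allele=list(counted) if counted else [v.effect_allele for v in panel],
        uncounted_allele=[v.other_allele for v in panel],
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
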