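"""Genotype input, effect-allele alignment and variant QC."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irgrs.genotypes import align_to_effect_allele, read_genotypes
from irgrs.panel import VariantRecord, WeightTable
from irgrs.qc import QCParams, filter_variants, genotype_counts, hardcalls, hwe_exact_test
from irgrs.simulate import make_panel, simulate_genotypes


# --------------------------------------------------------------------------- #
# Hardy-Weinberg exact test
# --------------------------------------------------------------------------- #

def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-arithmetic enumeration of the conditional heterozygote distribution.

    P(h) = n! 2^h / (n_AA! h! n_aa!) over all h with the parity of the minor
    allele count; the two-sided p sums probabilities <= that of the observed h.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    probs = {}
    total = Fraction(0)
    for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2):
        ha, hb = (n_a - h) // 2, (n_b - h) // 2
        # multinomial count of genotype tables times 2^h phase choices
        w = Fraction(2**h) * Fraction(
            comb(n, ha) * comb(n - ha, h)
        )
        probs[h] = w
        total += w
    p_obs = probs[n_het]
    tail = sum(w for w in probs.values() if w <= p_obs)
    return float(Fraction(tail, total))


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((1, 2, 1), 1.0),  # modal configuration of 4+4 alleles
        ((10, 0, 0), 1.0),  # monomorphic
        ((0, 0, 7), 1.0),
    ],
)
def test_hwe_exact_known_values(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_exact_matches_enumeration_oracle():
    assert hwe_exact_test(5, 25, 5) == pytest.approx(
        hwe_enumeration_oracle(5, 25, 5), abs=1e-12
    )


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
)
def test_hwe_exact_equals_oracle_property(a, h, b):
    """The implementation agrees with exact-fraction enumeration for N <= 50."""
    if a + h + b == 0 or a + h + b > 50:
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(
        hwe_enumeration_oracle(a, h, b), rel=1e-10, abs=1e-12
    )


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_calibration_on_simulated_genotypes(rng):
    """Under true HWE the 5% filter removes ~5% of variants."""
    panel = make_panel(400, rng)
    mafs = rng.uniform(0.1, 0.5, 400)
    mat = simulate_genotypes(800, mafs, panel, rng)
    fails = 0
    for j in range(mat.n_variants):
        hard = hardcalls(mat.dosage[:, j], mat.missing[:, j], 0.1)
        if hwe_exact_test(*genotype_counts(hard)) <= 0.05 and True:
            fails += 1
    frac = fails / 400
    # exact test is conservative: reject rate <= nominal, and within 3 binomial SE
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)


# --------------------------------------------------------------------------- #
# reading and alignment
# --------------------------------------------------------------------------- #

def test_read_tsv_dosages_and_missing(tmp_path, small_panel):
    path = tmp_path / "dose.tsv"
    path.write_text(
        "sample_id\trs1\trs2\trs3\nS1\t1.3\t\t0.0\nS2\t0.5\t2.0\t1.0\n"
    )
    mat = read_genotypes(path, small_panel, "tsv")
    assert mat.dosage[0, 0] == pytest.approx(1.3)
    assert mat.missing[0, 1] and not mat.missing[0, 0]
    assert mat.dosage[1, 2] == pytest.approx(1.0)


def test_read_tsv_rejects_out_of_range(tmp_path, small_panel):
    path = tmp_path / "dose.tsv"
    path.write_text("sample_id\trs1\trs2\trs3\nS1\t2.5\t1\t1\n")
    with pytest.raises(ValueError, match="rs1"):
        read_genotypes(path, small_panel, "tsv")


def test_read_vcf_dosage_and_hardcalls(tmp_path, small_panel):
    vcf = tmp_path / "g.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "2\t200\trs2\tT\tC\t.\tPASS\t.\tGT\t0/0\t./.\n"
    )
    mat = read_genotypes(vcf, small_panel, "vcf")
    assert mat.dosage[0, 0] == 1.0 and mat.dosage[1, 0] == 2.0
    assert mat.missing[1, 1]
    assert mat.missing[:, 2].all()  # rs3 absent from the file


def test_align_flips_other_allele_counts(small_panel, matrix_factory):
    # rs1 counted on the other allele G: d -> 2 - d
    mat = matrix_factory(small_panel, [[0.4, 1.0, 2.0]], counted=["G", "C", "G"])
    aligned = align_to_effect_allele(mat, small_panel)
    assert aligned.dosage[0, 0] == pytest.approx(1.6)
    assert aligned.dosage[0, 1] == pytest.approx(1.0)
    assert aligned.counted_allele[0] == "A"


def test_align_is_involution(small_panel, matrix_factory, rng):
    d = rng.uniform(0, 2, (20, 3))
    mat = matrix_factory(small_panel, d, counted=["G", "T", "A"])
    once = align_to_effect_allele(mat, small_panel)
    twice = align_to_effect_allele(once, small_panel)
    np.testing.assert_allclose(once.dosage, twice.dosage)
    # flipping relative to the original counted alleles restores the input
    np.testing.assert_allclose(2.0 - once.dosage, d)


def test_align_rejects_foreign_alleles(small_panel, matrix_factory):
    mat = matrix_factory(small_panel, [[1.0, 1.0, 1.0]], counted=["T", "C", "G"])
    with pytest.raises(ValueError, match="rs1"):
        align_to_effect_allele(mat, small_panel)


@pytest.mark.parametrize("policy, expect", [("drop", "missing"), ("error", "raises")])
def test_align_palindromic_policies(policy, expect):
    panel = WeightTable([VariantRecord("rsAT", "1", 1, "A", "T", 0.01)])
    from conftest import make_matrix

    mat = make_matrix(panel, [[1.2]], counted=["A"])
    if expect == "raises":
        with pytest.raises(ValueError, match="palindromic"):
            align_to_effect_allele(mat, panel, policy)
    else:
        out = align_to_effect_allele(mat, panel, policy)
        assert out.missing[0, 0]


# --------------------------------------------------------------------------- #
# filtering
# --------------------------------------------------------------------------- #

def _hwe_failing_column(rng, n=200):
    """All-heterozygote genotypes: extreme HWE violation."""
    return np.ones(n)


def test_filter_removes_hwe_failures(small_panel, matrix_factory, rng):
    n = 200
    d = np.column_stack(
        [
            rng.binomial(2, 0.3, n).astype(float),
            _hwe_failing_column(rng, n),
            rng.binomial(2, 0.4, n).astype(float),
        ]
    )
    mat = matrix_factory(small_panel, d)
    kept, report = filter_variants(mat, QCParams())
    assert report.loc[report.variant_id == "rs2", "pass"].item() is False
    assert "HWE" in report.loc[report.variant_id == "rs2", "reasons"].item()
    assert [v.variant_id for v in kept.variants] == ["rs1", "rs3"]
    # surviving dosages are untouched
    np.testing.assert_array_equal(kept.dosage, d[:, [0, 2]])


def test_filter_call_rate_and_info(small_panel, matrix_factory, rng):
    n = 100
    d = rng.binomial(2, 0.3, (n, 3)).astype(float)
    missing = np.zeros_like(d, dtype=bool)
    missing[: n // 2, 0] = True  # 50% call rate on rs1
    mat = matrix_factory(small_panel, d, missing=missing)
    kept, report = filter_variants(mat, QCParams(), info_scores=[0.99, 0.99, 0.90])
    reasons = dict(zip(report.variant_id, report.reasons))
    assert "call_rate" in reasons["rs1"]
    assert "info" in reasons["rs3"]
    assert [v.variant_id for v in kept.variants] == ["rs2"]


def test_filter_hwe_not_computable_policy(small_panel, matrix_factory):
    d = np.full((50, 3), 0.5)  # no hard calls at threshold 0.1
    mat = matrix_factory(small_panel, d)
    kept, report = filter_variants(mat, QCParams())
    assert report["hwe_p"].isna().all()
    assert kept.n_variants == 3  # retained by default
    kept2, _ = filter_variants(mat, QCParams(keep_hwe_uncomputable=False))
    assert kept2.n_variants == 0


def test_qc_params_validation():
    with pytest.raises(ValueError):
        QCParams(hwe_alpha=1.5)
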