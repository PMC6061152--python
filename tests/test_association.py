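"""The statistical engine: OLS fits, directionality, heterogeneity, FDR."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irgrs.association import (
    TraitConfig,
    assoc_grs,
    attach_fdr,
    bh_fdr,
    direction_binomial,
    fit_linear,
    heterogeneity_test,
    per_snp_assoc,
)
from irgrs.grs import unweighted_grs
from irgrs.simulate import make_panel, simulate_genotypes


# --------------------------------------------------------------------------- #
# OLS core
# --------------------------------------------------------------------------- #

def ols_normal_equations(y, X):
    """Independent oracle: betas and classical SEs from the normal equations."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    ses = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, ses, df


def test_fit_linear_exact_noiseless_fit():
    x = np.arange(10, dtype=float)
    X = np.column_stack([np.ones(10), x])
    y = 1.0 + 2.0 * x
    fit = fit_linear(y, X)
    np.testing.assert_allclose(fit.betas, [1.0, 2.0], atol=1e-12)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    np.testing.assert_allclose(fit.ses, 0.0, atol=1e-12)  # degenerate: zero SEs


@pytest.mark.parametrize("seed", range(5))
def test_fit_linear_matches_normal_equations_and_statsmodels(seed):
    rng = np.random.default_rng(seed)
    n, k = 50, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    y = X @ rng.normal(size=k) + rng.normal(size=n)
    fit = fit_linear(y, X)
    beta_o, ses_o, df_o = ols_normal_equations(y, X)
    np.testing.assert_allclose(fit.betas, beta_o, atol=1e-10)
    np.testing.assert_allclose(fit.ses, ses_o, atol=1e-10)
    assert fit.df == df_o

    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.betas, res.params, atol=1e-10)
    np.testing.assert_allclose(fit.ses, res.bse, atol=1e-10)
    np.testing.assert_allclose(fit.p_values, res.pvalues, atol=1e-10)


def test_fit_linear_rank_deficiency_names_columns():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    X = np.column_stack([np.ones(30), x, x])  # duplicated column
    with pytest.raises(ValueError, match="collinear"):
        fit_linear(rng.normal(size=30), X, ["intercept", "a", "a_copy"])


def test_fit_linear_rejects_missing_and_underdetermined():
    with pytest.raises(ValueError, match="complete"):
        fit_linear(np.array([1.0, np.nan]), np.ones((2, 1)))
    with pytest.raises(ValueError, match="observations"):
        fit_linear(np.ones(2), np.ones((2, 3)))


# --------------------------------------------------------------------------- #
# GRS association
# --------------------------------------------------------------------------- #

def _toy_pheno(rng, n=300, trait="homa_ir", beta=0.0, sigma=1.0, log_trait=False):
    grs = rng.normal(28, 4.5, n)
    age = rng.uniform(6, 18, n)
    sex = rng.choice(["male", "female"], n)
    lat = 1.0 + beta * grs + 0.01 * age + sigma * rng.standard_normal(n)
    vals = 10.0**lat if log_trait else lat
    pheno = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "cohort": "clinical",
            "age": age,
            "sex": sex,
            trait: vals,
        }
    )
    scores = pd.DataFrame({"sample_id": pheno.sample_id, "grs_unweighted": grs})
    return pheno, scores


def test_assoc_grs_transform_flag_off_has_no_p_log(rng):
    pheno, scores = _toy_pheno(rng)
    res = assoc_grs(pheno, scores, TraitConfig("homa_ir", False, ("age", "sex")))
    assert res.p_log is None
    assert res.p_report == res.p_raw


def test_assoc_grs_log_fit_matches_direct_fit(rng):
    """p_log equals an explicit OLS on log10(trait); beta comes from raw trait."""
    pheno, scores = _toy_pheno(rng, log_trait=True)
    cfg = TraitConfig("homa_ir", True, ("age", "sex"))
    res = assoc_grs(pheno, scores, cfg)

    frame = pheno.merge(scores, on="sample_id")
    X = np.column_stack(
        [
            np.ones(len(frame)),
            frame.grs_unweighted,
            frame.age,
            (frame.sex == "female").astype(float),
        ]
    )
    fit_raw = fit_linear(frame.homa_ir.to_numpy(), X)
    fit_log = fit_linear(np.log10(frame.homa_ir.to_numpy()), X)
    assert res.beta == pytest.approx(fit_raw.betas[1], rel=1e-12)
    assert res.p_log == pytest.approx(fit_log.p_values[1], rel=1e-12)


def test_assoc_grs_rejects_log_of_nonpositive(rng):
    pheno, scores = _toy_pheno(rng)
    pheno.loc[3, "homa_ir"] = -0.5
    with pytest.raises(ValueError, match="non-positive"):
        assoc_grs(pheno, scores, TraitConfig("homa_ir", True, ("age", "sex")))


def test_assoc_grs_recovers_planted_effect(rng):
    """A planted 0.1-per-GRS-unit effect is recovered without bias: the mean
    estimate over replicates sits within 3 SE of the mean of the truth."""
    reps, betas, ses = 10, [], []
    for _ in range(reps):
        pheno, scores = _toy_pheno(rng, n=700, beta=0.1, sigma=1.0)
        res = assoc_grs(pheno, scores, TraitConfig("homa_ir", False, ("age", "sex")))
        betas.append(res.beta)
        ses.append(res.se)
    se_mean = np.mean(ses) / np.sqrt(reps)
    assert abs(np.mean(betas) - 0.1) < 3 * se_mean


def test_assoc_grs_sensitivity_exclusion(rng):
    pheno, scores = _toy_pheno(rng)
    pheno["exclusion_flag"] = False
    pheno.loc[:28, "exclusion_flag"] = True
    res_all = assoc_grs(pheno, scores, TraitConfig("homa_ir"), drop_excluded=False)
    res_sens = assoc_grs(pheno, scores, TraitConfig("homa_ir"), drop_excluded=True)
    assert res_all.n - res_sens.n == 29


# --------------------------------------------------------------------------- #
# per-SNP associations
# --------------------------------------------------------------------------- #

def test_per_snp_skips_zero_variance_and_orders_by_panel(rng):
    panel = make_panel(5, rng)
    mat = simulate_genotypes(200, np.full(5, 0.3), panel, rng)
    mat.dosage[:, 2] = 1.0  # constant dosage -> unidentifiable
    pheno = pd.DataFrame(
        {
            "sample_id": mat.sample_ids,
            "age": rng.uniform(6, 18, 200),
            "sex": rng.choice(["male", "female"], 200),
            "trait": rng.standard_normal(200),
        }
    )
    results = per_snp_assoc(mat, pheno, TraitConfig("trait", False, ("age", "sex")))
    ids = [r.predictor for r in results]
    assert ids == [v.variant_id for v in panel.variants if v.variant_id != panel[2].variant_id]


def test_per_snp_planted_causal_snp_is_top_hit(rng):
    """One causal SNP (beta 0.3, MAF 0.3, n = 2000) has the panel-minimum p
    in nearly all replicates."""
    hits = 0
    reps = 25
    for _ in range(reps):
        panel = make_panel(20, rng)
        mat = simulate_genotypes(2000, np.full(20, 0.3), panel, rng)
        y = 0.3 * mat.dosage[:, 7] + rng.standard_normal(2000)
        pheno = pd.DataFrame({"sample_id": mat.sample_ids, "trait": y})
        results = per_snp_assoc(mat, pheno, TraitConfig("trait"))
        best = min(results, key=lambda r: r.p_raw)
        hits += best.predictor == panel[7].variant_id
    assert hits >= int(0.9 * reps)


# --------------------------------------------------------------------------- #
# directionality binomial test
# --------------------------------------------------------------------------- #

def binomial_two_sided_oracle(k, n):
    """Sum of Binomial(n, 1/2) outcome probabilities <= P(k)."""
    pmf = [comb(n, i) for i in range(n + 1)]
    p_obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= p_obs) / 2**n)


def test_direction_binomial_published_example():
    """38 of 53 consistent signs -> p = 2.19e-3 (3 significant figures)."""
    signs = np.concatenate([-np.ones(38), np.ones(15)]).astype(int)
    k, n, p = direction_binomial(signs, -1)
    assert (k, n) == (38, 53)
    assert p == pytest.approx(2.19e-3, rel=5e-3)


def test_direction_binomial_symmetry_and_extreme():
    k, n, p = direction_binomial([1] * 27 + [-1] * 26, 1)
    assert p == pytest.approx(1.0)
    _, _, p_all = direction_binomial([1] * 53, 1)
    assert p_all == pytest.approx(2.0**-52, rel=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=60), st.data())
def test_direction_binomial_matches_pmf_oracle(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    signs = [1] * k + [-1] * (n - k)
    _, _, p = direction_binomial(signs, 1)
    assert p == pytest.approx(binomial_two_sided_oracle(k, n), rel=1e-12)


def test_direction_binomial_input_validation():
    with pytest.raises(ValueError):
        direction_binomial([], 1)
    with pytest.raises(ValueError):
        direction_binomial([0, 1], 1)


# --------------------------------------------------------------------------- #
# heterogeneity test
# --------------------------------------------------------------------------- #

def test_heterogeneity_equal_betas():
    _, p = heterogeneity_test(0.5, 0.1, 0.5, 0.2)
    assert p == pytest.approx(1.0)


def test_heterogeneity_hand_example():
    z, p = heterogeneity_test(0.109, 0.050, 0.021, 0.012)
    assert z == pytest.approx(1.711, abs=5e-4)
    assert p == pytest.approx(0.087, abs=5e-4)


def test_heterogeneity_antisymmetry_and_scale_invariance():
    z1, p1 = heterogeneity_test(0.3, 0.05, 0.1, 0.04)
    z2, p2 = heterogeneity_test(0.1, 0.04, 0.3, 0.05)
    assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)
    z3, p3 = heterogeneity_test(3.0, 0.5, 1.0, 0.4)  # common x10 rescale
    assert z3 == pytest.approx(z1) and p3 == pytest.approx(p1)


def test_heterogeneity_infinite_se_limit_and_validation():
    _, p = heterogeneity_test(0.3, 0.05, -0.2, 1e6)
    assert p == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError):
        heterogeneity_test(0.1, 0.0, 0.1, 0.1)


def test_heterogeneity_welch_df():
    z_n, p_n = heterogeneity_test(0.3, 0.1, 0.1, 0.1)
    z_w, p_w = heterogeneity_test(0.3, 0.1, 0.1, 0.1, df_mode="welch", n1=20, n2=20)
    assert z_w == pytest.approx(z_n)
    assert p_w > p_n  # t tails are heavier


# --------------------------------------------------------------------------- #
# Benjamini-Hochberg FDR
# --------------------------------------------------------------------------- #

def bh_reject_oracle(p, q):
    """Classic step-up cutoff: reject the r smallest where r is the largest
    rank with p_(r) <= q r / n."""
    p = np.asarray(p)
    order = np.argsort(p)
    n = len(p)
    r_max = 0
    for r in range(1, n + 1):
        if p[order[r - 1]] <= q * r / n:
            r_max = r
    reject = np.zeros(n, dtype=bool)
    reject[order[:r_max]] = True
    return reject


def test_bh_fdr_examples():
    adj, _ = bh_fdr([0.03])
    assert adj[0] == pytest.approx(0.03)
    adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.10)
    np.testing.assert_allclose(adj, 0.04)
    assert rej.all()
    adj, _ = bh_fdr([0.2, 0.2, 0.2])
    np.testing.assert_allclose(adj, 0.2)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
def test_bh_fdr_matches_cutoff_oracle_and_monotone(p):
    q = 0.10
    adj, rej = bh_fdr(p, q)
    np.testing.assert_array_equal(rej, bh_reject_oracle(p, q))
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in raw-p rank
    assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-15)


def test_bh_fdr_validation():
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_fdr([])


def test_attach_fdr_uses_reported_p(rng):
    pheno, scores = _toy_pheno(rng, log_trait=True)
    res = [
        assoc_grs(pheno, scores, TraitConfig("homa_ir", True, ("age", "sex"))),
        assoc_grs(pheno, scores, TraitConfig("homa_ir", False, ("age", "sex"))),
    ]
    attach_fdr(res)
    assert all(r.p_fdr is not None for r in res)
    adj, _ = bh_fdr([res[0].p_log, res[1].p_raw])
    assert res[0].p_fdr == pytest.approx(adj[0])
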