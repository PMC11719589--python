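import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugpgs import (associate_all, compute_maf, fit_logistic_logadditive,
                     hwe_exact_test, ld_r2, prune_by_ld, qc_report)
from drugpgs.assoc_qc import UndefinedValueError, genotype_counts
from drugpgs.io_formats import GenotypeDataset

from conftest import hwe_enumeration_oracle


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def test_compute_maf_arithmetic_and_boundaries():
    freq, maf = compute_maf([0, 1, 1, 2])
    assert freq == 0.5 and maf == 0.5
    _, maf0 = compute_maf([0, 0, 0])
    assert maf0 == 0.0
    freq, maf = compute_maf([2, 2, 1, np.nan])  # missing excluded
    assert freq == pytest.approx(5 / 6)
    assert maf == pytest.approx(1 / 6)
    with pytest.raises(UndefinedValueError):
        compute_maf([np.nan, np.nan])


def test_control_maf_recovers_simulation_frequency(null_dataset, panel):
    q = panel.row("rs11123610").maf_reference  # 0.3783
    ctrl = null_dataset.dosages[null_dataset.phenotype == 0,
                                null_dataset.snp_ids.index("rs11123610")]
    _, maf = compute_maf(ctrl)
    se = np.sqrt(q * (1 - q) / (2 * ctrl.size))
    assert abs(maf - q) < 3 * se


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(0, 0, 57) == 1.0
    assert hwe_exact_test(57, 0, 0) == 1.0


def test_hwe_two_individual_enumeration():
    # configurations with 2 minor alleles in n=2: (1,0,1) weight 2, (0,2,0)
    # weight 4 -> p(observed (1,0,1)) = 2/6
    assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)


@given(st.integers(0, 16), st.integers(0, 16), st.integers(0, 16))
@settings(max_examples=200, deadline=None)
def test_hwe_matches_rational_enumeration_oracle(a, b, c):
    if a + b + c == 0:
        return
    assert hwe_exact_test(a, b, c) == pytest.approx(
        hwe_enumeration_oracle(a, b, c), abs=1e-12)


def test_genotype_counts_folds_to_minor_allele():
    # counted allele at frequency 0.75 -> fold so 'minor-hom' means
    # homozygous for the rarer allele
    d = [2, 2, 2, 1, 0, 2]
    assert genotype_counts(d) == (1, 1, 4)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def test_ld_r2_identity_and_hand_value():
    assert ld_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)
    # cov = 0.3125, both variances 0.6875 -> r2 = (0.3125/0.6875)^2
    assert ld_r2([0, 1, 2, 0], [0, 1, 2, 2]) == pytest.approx(0.20661157,
                                                              abs=1e-8)
    with pytest.raises(UndefinedValueError):
        ld_r2([1, 1, 1], [0, 1, 2])
    with pytest.raises(UndefinedValueError):
        ld_r2([0, np.nan, np.nan], [0, 1, 2])


def test_independent_snps_have_near_zero_r2():
    rng = np.random.default_rng(21)
    n, hits = 5_000, 0
    for _ in range(100):
        a = rng.binomial(2, 0.3, n).astype(float)
        b = rng.binomial(2, 0.3, n).astype(float)
        hits += ld_r2(a, b) < 0.01
    assert hits >= 99  # null r2 ~ 1/n


def _dataset_from_columns(cols, phenotype):
    cols = {k: np.asarray(v, float) for k, v in cols.items()}
    ids = list(cols)
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(len(phenotype))],
        snp_ids=ids,
        dosages=np.column_stack([cols[k] for k in ids]),
        counted_alleles=["A"] * len(ids),
        other_alleles=["G"] * len(ids),
        phenotype=np.asarray(phenotype, int),
    )


def test_prune_keeps_all_when_uncorrelated(null_dataset):
    assoc = associate_all(null_dataset)
    pvals = dict(zip(assoc.snp_id, assoc.p))
    kept, removed = prune_by_ld(null_dataset, pvals, threshold=0.2)
    assert kept == null_dataset.snp_ids  # independent by construction
    assert removed.empty


def test_prune_duplicate_column_keeps_smaller_p():
    rng = np.random.default_rng(22)
    g = rng.binomial(2, 0.4, 400).astype(float)
    other = rng.binomial(2, 0.4, 400).astype(float)
    y = rng.integers(0, 2, 400)
    ds = _dataset_from_columns({"dup1": g, "dup2": g, "free": other}, y)
    pvals = {"dup1": 0.5, "dup2": 0.01, "free": 0.9}
    kept, removed = prune_by_ld(ds, pvals, threshold=0.2)
    assert "dup2" in kept and "dup1" not in kept
    assert removed.iloc[0]["snp_id"] == "dup1"
    assert removed.iloc[0]["r2"] == pytest.approx(1.0)


def test_prune_mutually_correlated_triple_keeps_exactly_one():
    rng = np.random.default_rng(23)
    base = rng.binomial(2, 0.5, 1_000).astype(float)
    noisy = lambda: np.clip(base + (rng.random(1_000) < 0.03) *
                            rng.choice([-1, 1], 1_000), 0, 2)
    ds = _dataset_from_columns({"a": base, "b": noisy(), "c": noisy()},
                               rng.integers(0, 2, 1_000))
    pvals = {"a": 0.1, "b": 0.2, "c": 0.3}
    kept, _ = prune_by_ld(ds, pvals, threshold=0.2)
    assert kept == ["a"]


# ---------------------------------------------------------------------------
# logistic association
# ---------------------------------------------------------------------------

def _binary_dosage_data(a, b, c, d):
    """2x2 layout: a carriers among cases, b non-carriers among cases,
    c carriers among controls, d non-carriers among controls."""
    g = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return g, y


def test_logistic_matches_2x2_closed_form():
    g, y = _binary_dosage_data(30, 70, 10, 90)
    res = fit_logistic_logadditive(g, y, snp_id="rs_test")
    assert res.converged
    assert res.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
    assert res.se == pytest.approx(np.sqrt(1/30 + 1/70 + 1/10 + 1/90),
                                   abs=1e-6)
    assert res.n_used == 200
    # Wald identity: p is the two-sided normal tail of beta/se
    from scipy.stats import norm
    assert res.p == pytest.approx(2 * norm.sf(abs(res.beta / res.se)),
                                  abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000))
def test_logistic_matches_independent_ml_optimizer(seed):
    """IRLS fit agrees with statsmodels' generic Logit MLE."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    n = rng.integers(60, 500)
    g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    y = rng.binomial(1, 0.3 + 0.4 * (g > 0), n).astype(float)
    if len(np.unique(y)) < 2 or np.var(g) == 0:
        return
    res = fit_logistic_logadditive(g, y)
    if not res.converged:
        return
    sm_fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0, method="newton")
    assert res.beta == pytest.approx(sm_fit.params[1], abs=1e-6)
    assert res.se == pytest.approx(sm_fit.bse[1], abs=1e-6)


def test_allele_flip_negates_beta_and_preserves_se():
    rng = np.random.default_rng(31)
    g = rng.binomial(2, 0.3, 500).astype(float)
    y = rng.binomial(1, 0.3 + 0.1 * g, 500)
    r1 = fit_logistic_logadditive(g, y)
    r2 = fit_logistic_logadditive(2 - g, y)
    assert r2.beta == pytest.approx(-r1.beta, abs=1e-8)
    assert r2.se == pytest.approx(r1.se, abs=1e-8)


def test_missing_dosages_are_dropped_per_snp():
    g, y = _binary_dosage_data(30, 70, 10, 90)
    g_miss = g.copy()
    g_miss[:5] = np.nan
    res = fit_logistic_logadditive(g_miss, y)
    assert res.n_used == 195


def test_separation_is_flagged_never_silent():
    g = np.r_[np.ones(20) * 2, np.zeros(20)]
    y = np.r_[np.ones(20), np.zeros(20)]
    res = fit_logistic_logadditive(g, y)
    assert not res.converged
    assert np.isnan(res.p)


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError, match="monomorphic"):
        fit_logistic_logadditive(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
    with pytest.raises(ValueError, match="case and one control"):
        fit_logistic_logadditive(np.r_[np.zeros(5), np.ones(5)], np.ones(10))


def test_true_effect_recovered_in_association_table(small_dataset):
    assoc = associate_all(small_dataset).set_index("snp_id")
    hit = assoc.loc["rs295137"]
    assert hit.converged
    assert abs(hit.beta - 0.47) < 3 * hit.se
    null_p = assoc.drop(["rs295137", "rs2395672"])["p"]
    assert (null_p > 1e-4).all()  # no wild null inflation in one draw


def test_qc_report_contents(small_dataset):
    qc = qc_report(small_dataset)
    assert len(qc) == 26
    assert ((qc.maf_controls >= 0) & (qc.maf_controls <= 0.5)).all()
    assert ((qc.hwe_p > 0) & (qc.hwe_p <= 1)).all()
    assert (qc.call_rate == 1.0).all()
    with pytest.raises(ValueError):
        qc_report(small_dataset, hwe_on="cases")
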