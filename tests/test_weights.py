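import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drugpgs import (StudyEffect, TAGC_PROXY_PAIRS, assign_risk_allele,
                     build_weight_set, meta_fixed_effect,
                     remove_study_from_meta)
from drugpgs.weights import MetaInversionError


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis and its inversion
# ---------------------------------------------------------------------------

def test_meta_single_study_is_identity():
    assert meta_fixed_effect([StudyEffect(0.3, 0.12)]) == \
        pytest.approx((0.3, 0.12))


def test_meta_hand_evaluated_example():
    m = meta_fixed_effect([StudyEffect(0.2, 0.1), StudyEffect(0.4, 0.2)])
    assert m.beta == pytest.approx(0.24, abs=1e-12)       # weights 100, 25
    assert m.se == pytest.approx(0.08944272, abs=1e-7)


def test_meta_k_identical_studies_shrinks_se_by_sqrt_k():
    k = 7
    m = meta_fixed_effect([StudyEffect(0.3, 0.2)] * k)
    assert m.beta == pytest.approx(0.3)
    assert m.se == pytest.approx(0.2 / np.sqrt(k))


def test_remove_study_inverts_the_example():
    m = meta_fixed_effect([StudyEffect(0.2, 0.1), StudyEffect(0.4, 0.2)])
    back = remove_study_from_meta(m, StudyEffect(0.4, 0.2))
    assert back.beta == pytest.approx(0.2, abs=1e-12)
    assert back.se == pytest.approx(0.1, abs=1e-12)


def test_remove_zero_weight_study_leaves_meta_unchanged():
    m = StudyEffect(0.24, 0.09)
    back = remove_study_from_meta(m, StudyEffect(5.0, 1e9))
    assert back.beta == pytest.approx(m.beta, abs=1e-9)
    assert back.se == pytest.approx(m.se, abs=1e-9)


def test_remove_dominant_or_only_study_is_non_invertible():
    with pytest.raises(MetaInversionError):
        remove_study_from_meta(StudyEffect(0.2, 0.1), StudyEffect(0.2, 0.1))
    with pytest.raises(MetaInversionError):
        remove_study_from_meta(StudyEffect(0.2, 0.1), StudyEffect(0.2, 0.05))


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 10_000))
def test_loo_equals_meta_of_remaining_studies(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(3, 11)
    studies = [StudyEffect(rng.uniform(-1, 1), rng.uniform(0.01, 1.0))
               for _ in range(k)]
    full = meta_fixed_effect(studies)
    for i in range(k):
        loo = remove_study_from_meta(full, studies[i])
        rest = meta_fixed_effect(studies[:i] + studies[i + 1:])
        assert loo.beta == pytest.approx(rest.beta, abs=1e-10)
        assert loo.se == pytest.approx(rest.se, abs=1e-10)


# ---------------------------------------------------------------------------
# risk-allele orientation
# ---------------------------------------------------------------------------

def test_risk_allele_orientation_rules():
    assert assign_risk_allele(0.4707, "T", "C") == ("T", 0.4707)
    assert assign_risk_allele(-0.3, "A", "G") == ("G", 0.3)
    assert assign_risk_allele(0.0, "A", "G") == ("A", 0.0)  # tie rule


# ---------------------------------------------------------------------------
# weight-set construction
# ---------------------------------------------------------------------------

def _local_assoc(panel, rng):
    return pd.DataFrame({
        "snp_id": panel.snp_ids,
        "beta": rng.normal(0, 0.3, len(panel)),
        "converged": True,
    })


def _summary_for(panel, snp_ids, betas, ses):
    rows = []
    for s, b, se in zip(snp_ids, betas, ses):
        try:
            prow = panel.row(s)
            ea, oa = prow.counted_allele, prow.other_allele
        except KeyError:
            ea, oa = "A", "G"
        rows.append({"snp_id": s, "effect_allele": ea, "other_allele": oa,
                     "beta": b, "se": se, "n": 100000})
    return pd.DataFrame(rows)


def test_local_mode_weights_are_absolute_local_betas(panel):
    rng = np.random.default_rng(41)
    la = _local_assoc(panel, rng)
    ws, dropped = build_weight_set(panel, la, mode="local")
    assert dropped == []
    assert len(ws) == 26
    np.testing.assert_allclose(ws.weight, np.abs(la.beta))
    assert (ws.weight >= 0).all()
    assert (ws.source == "local").all()


def test_seven_absent_snps_resolved_through_stated_proxies(panel):
    rng = np.random.default_rng(42)
    la = _local_assoc(panel, rng)
    absent = [m for m, _ in TAGC_PROXY_PAIRS]
    present = [s for s in panel.snp_ids if s not in absent]
    proxies = [p for _, p in TAGC_PROXY_PAIRS]
    ss = _summary_for(panel, present + proxies,
                      rng.normal(0, 0.1, len(present) + 7),
                      rng.uniform(0.01, 0.05, len(present) + 7))
    proxy_map = [(m, p, 0.9) for m, p in TAGC_PROXY_PAIRS]
    ws, dropped = build_weight_set(panel, la, summary_stats=ss,
                                   proxy_map=proxy_map, mode="gwas_corrected")
    assert dropped == []
    src = ws.set_index("snp_id")["source"]
    assert (src.loc[present] == "gwas_corrected").all()
    for m, p in TAGC_PROXY_PAIRS:
        assert src.loc[m] == f"proxy:{p}"
    assert (src == "gwas_corrected").sum() == 19
    assert src.str.startswith("proxy:").sum() == 7


def test_no_proxies_needed_when_all_snps_present(panel):
    rng = np.random.default_rng(43)
    la = _local_assoc(panel, rng)
    ss = _summary_for(panel, panel.snp_ids, rng.normal(0, 0.1, 26),
                      rng.uniform(0.01, 0.05, 26))
    ws, dropped = build_weight_set(panel, la, summary_stats=ss,
                                   proxy_map=[(s, "rs0", 0.99) for s in
                                              panel.snp_ids],
                                   mode="gwas_corrected")
    assert dropped == []
    assert not ws.source.str.startswith("proxy").any()


def test_low_r2_proxy_dropped_with_accounting(panel):
    rng = np.random.default_rng(44)
    la = _local_assoc(panel, rng)
    present = panel.snp_ids[1:]
    ss = _summary_for(panel, present, rng.normal(0, 0.1, 25),
                      rng.uniform(0.01, 0.05, 25))
    missing = panel.snp_ids[0]
    ws, dropped = build_weight_set(
        panel, la, summary_stats=ss,
        proxy_map=[(missing, present[0], 0.5)],  # below 0.8 threshold
        mode="gwas_corrected")
    assert dropped == [missing]
    assert len(ws) + len(dropped) == len(panel)
    # reachable with the permissive threshold the printed r2 > 0.08 implies
    ws2, dropped2 = build_weight_set(
        panel, la, summary_stats=ss,
        proxy_map=[(missing, present[0], 0.5)],
        mode="gwas_corrected", proxy_threshold=0.08)
    assert dropped2 == []


def test_loo_corrected_weights_recover_removed_cohort_complement(panel):
    """summary stats = meta(cohortA, cohortB); removing cohortB must leave
    exactly |beta_A| as the weight."""
    rng = np.random.default_rng(45)
    la = _local_assoc(panel, rng)
    bA = rng.normal(0, 0.2, 26)
    sA = rng.uniform(0.05, 0.3, 26)
    bB = rng.normal(0, 0.2, 26)
    sB = rng.uniform(0.05, 0.3, 26)
    meta = [meta_fixed_effect([StudyEffect(a, x), StudyEffect(b, y)])
            for a, x, b, y in zip(bA, sA, bB, sB)]
    ss = _summary_for(panel, panel.snp_ids, [m.beta for m in meta],
                      [m.se for m in meta])
    removed = _summary_for(panel, panel.snp_ids, bB, sB)
    ws, _ = build_weight_set(panel, la, summary_stats=ss,
                             removed_cohort=removed, mode="gwas_corrected")
    np.testing.assert_allclose(ws.weight.to_numpy(), np.abs(bA), atol=1e-10)


def test_external_beta_sign_flipped_onto_counted_frame(panel):
    """External stats reporting the other allele as effect allele must be
    sign-flipped before use."""
    rng = np.random.default_rng(46)
    la = _local_assoc(panel, rng)
    ss = _summary_for(panel, panel.snp_ids, np.full(26, 0.25),
                      np.full(26, 0.1))
    row0 = panel.table.iloc[0]
    ss.loc[0, ["effect_allele", "other_allele"]] = \
        [row0.other_allele, row0.counted_allele]
    ws, _ = build_weight_set(panel, la, summary_stats=ss,
                             mode="gwas_corrected")
    b0 = ws.set_index("snp_id").loc[row0.snp_id, "beta_origin"]
    assert b0 == pytest.approx(-0.25)

    ss.loc[0, ["effect_allele", "other_allele"]] = ["X", "Y"]
    with pytest.raises(ValueError, match="either orientation"):
        build_weight_set(panel, la, summary_stats=ss, mode="gwas_corrected")


def test_weight_set_requirements(panel):
    rng = np.random.default_rng(47)
    la = _local_assoc(panel, rng)
    with pytest.raises(ValueError, match="summary statistics"):
        build_weight_set(panel, la, mode="gwas_corrected")
    with pytest.raises(ValueError, match="missing"):
        build_weight_set(panel, la.iloc[:10], mode="local")
    la_bad = la.copy()
    la_bad.loc[0, "converged"] = False
    with pytest.raises(ValueError, match="converge"):
        build_weight_set(panel, la_bad, mode="local")
    # every SNP absent and no proxies -> empty weight set is an error
    ss = _summary_for(panel, ["rs_nowhere"], [0.1], [0.1])
    with pytest.raises(ValueError, match="empty"):
        build_weight_set(panel, la, summary_stats=ss, mode="gwas_corrected")
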