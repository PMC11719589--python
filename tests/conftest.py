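import numpy as np
import pandas as pd
import pytest

from drugpgs import SimConfig, VariantPanel, default_panel, simulate_case_control


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_dataset():
    """378/504 case-control draw with two truly associated SNPs."""
    cfg = SimConfig(seed=11, effects={"rs295137": 0.47, "rs2395672": 0.44})
    return simulate_case_control(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Null draw (no genetic effects) at the default group sizes."""
    return simulate_case_control(SimConfig(seed=12))


def make_panel(rows):
    """Build a panel from (snp_id, counted, other, maf) tuples."""
    return VariantPanel(pd.DataFrame({
        "snp_id": [r[0] for r in rows],
        "chrom": ["1"] * len(rows),
        "pos": list(range(1, len(rows) + 1)),
        "counted_allele": [r[1] for r in rows],
        "other_allele": [r[2] for r in rows],
        "maf_reference": [r[3] for r in rows],
        "gene": [""] * len(rows),
    }))


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney AUC with ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases, ctrls = s[y == 1], s[y == 0]
    gt = (cases[:, None] > ctrls[None, :]).sum()
    eq = (cases[:, None] == ctrls[None, :]).sum()
    return (gt + 0.5 * eq) / (cases.size * ctrls.size)


def hwe_enumeration_oracle(n_hom_minor, n_het, n_hom_major):
    """Exact-rational HWE p-value by enumerating heterozygote counts."""
    from fractions import Fraction
    from math import factorial

    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    weights = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        a = (n_minor - het) // 2
        c = n - a - het
        weights[het] = Fraction(
            factorial(n) * 2**het,
            factorial(a) * factorial(het) * factorial(c))
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)
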