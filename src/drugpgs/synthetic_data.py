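"""Case/control genotype simulator matching the analysis assumptions.

Genotypes are drawn in Hardy-Weinberg equilibrium at the panel's reference
allele frequencies (two independent Bernoulli haplotypes per individual, so
genotype probabilities are exactly ((1-q)^2, 2q(1-q), q^2)).  Disease status
follows the same log-additive logistic model the association stage fits:

    P(case | g) = expit(intercept + sum_j effect_j * g_j)

Individuals are accumulated by rejection sampling until the configured
case and control counts are reached, mirroring retrospective case/control
ascertainment with fixed group sizes.  Optional LD proxy pairs are built at
the haplotype level: the proxy haplotype copies the source haplotype with a
mixing probability calibrated so the population dosage correlation hits the
requested r-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_formats import GenotypeDataset, VariantPanel, default_panel

DEFAULT_SEED = 26  # one per panel SNP; keeps fixtures stable

#: Default group sizes of the study design this simulator emulates:
#: 378 childhood-onset cases (174 of them moderate-to-severe) / 504 controls.
DEFAULT_N_CASES = 378
DEFAULT_N_CONTROLS = 504
DEFAULT_SEVERITY_FRACTION = 174 / 378


class SimulationYieldError(RuntimeError):
    """A stratum is essentially unreachable under the disease model."""


@dataclass
class SimConfig:
    """Parameters of one simulated case/control study.

    ``effects`` maps snp_id -> log-odds per counted-allele copy (absent SNPs
    have effect 0); ``intercept`` is the baseline log-odds of disease;
    ``ld_pairs`` entries are ``(snp_id, proxy_id, target_r2)``.
    """

    panel: VariantPanel = field(default_factory=default_panel)
    effects: dict[str, float] = field(default_factory=dict)
    intercept: float = -0.29
    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    severity_fraction: float = DEFAULT_SEVERITY_FRACTION
    missing_rate: float = 0.0
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("n_cases and n_controls must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.severity_fraction <= 1:
            raise ValueError("severity_fraction must be in [0, 1]")
        for snp, proxy, r2 in self.ld_pairs:
            if not 0 <= r2 <= 1:
                raise ValueError(f"target r2 for ({snp}, {proxy}) not in [0, 1]")
        for snp, eff in self.effects.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for {snp}")
            if snp not in self.panel.snp_ids:
                raise ValueError(f"effect given for unknown SNP {snp}")

    @property
    def effect_vector(self) -> np.ndarray:
        return np.array([self.effects.get(s, 0.0) for s in self.panel.snp_ids])


def _mixing_probability(r: float, q_src: float, q_proxy: float) -> float:
    """Haplotype copy probability giving allele correlation ``r``."""
    if q_src in (0.0, 1.0) or q_proxy in (0.0, 1.0):
        raise ValueError("LD pair requires polymorphic frequencies")
    c = r * np.sqrt(q_proxy * (1 - q_proxy) / (q_src * (1 - q_src)))
    if not 0 <= c <= 1:
        raise ValueError(f"target r2 unreachable for frequencies "
                         f"{q_src:.3f}/{q_proxy:.3f}")
    resid = (q_proxy - c * q_src) / (1 - c) if c < 1 else 0.0
    if not -1e-12 <= resid <= 1 + 1e-12:
        raise ValueError("LD mixing residual frequency outside [0, 1]")
    return c, min(max(resid, 0.0), 1.0)


def simulate_genotypes(config: SimConfig, n: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` individuals' dosages (no phenotype, no missingness).

    Each SNP is i.i.d. across individuals with HWE genotype probabilities at
    its ``maf_reference``; SNPs named as LD proxies are re-generated from the
    source SNP's haplotypes at the calibrated mixing rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.panel
    q = panel.table["maf_reference"].to_numpy(float)
    m = len(panel)
    # two haplotypes per individual so LD is a population-level parameter
    hap1 = rng.random((n, m)) < q
    hap2 = rng.random((n, m)) < q

    idx = {s: j for j, s in enumerate(panel.snp_ids)}
    for snp, proxy, r2 in config.ld_pairs:
        if snp not in idx:
            raise ValueError(f"LD source {snp} not in panel")
        if proxy not in idx:
            raise ValueError(f"LD proxy {proxy} not in panel")
        j_src, j_px = idx[snp], idx[proxy]
        c, resid = _mixing_probability(np.sqrt(r2), q[j_src], q[j_px])
        for hap in (hap1, hap2):
            copy = rng.random(n) < c
            fresh = rng.random(n) < resid
            hap[:, j_px] = np.where(copy, hap[:, j_src], fresh)
    return (hap1.astype(float) + hap2.astype(float))


def _case_probability(config: SimConfig, dosages: np.ndarray) -> np.ndarray:
    return expit(config.intercept + dosages @ config.effect_vector)


def simulate_case_control(config: SimConfig) -> GenotypeDataset:
    """Simulate a full case/control dataset at the configured group sizes.

    Disease status is Bernoulli under the logistic model; batches are drawn
    and individuals kept by stratum until both targets are met (rejection
    sampling).  Severity labels are assigned to a random subset of cases at
    ``severity_fraction``; missingness is applied uniformly at
    ``missing_rate``.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = len(config.panel)
    need = {0: config.n_controls, 1: config.n_cases}
    kept = {0: [], 1: []}
    batch = max(1024, 2 * (config.n_cases + config.n_controls))
    drawn = 0
    while need[0] > len(kept[0]) or need[1] > len(kept[1]):
        g = simulate_genotypes(config, batch, rng)
        p = _case_probability(config, g)
        y = rng.random(batch) < p
        for label in (0, 1):
            want = need[label] - len(kept[label])
            if want > 0:
                rows = g[y == bool(label)][:want]
                kept[label].extend(rows)
        drawn += batch
        for label in (0, 1):
            short = need[label] - len(kept[label])
            if short > 0 and drawn >= 50 * batch:
                rate = (len(kept[label]) + 1) / drawn
                if rate < 1e-6:
                    raise SimulationYieldError(
                        f"stratum {label} yield ~{rate:.2e} per draw under "
                        f"intercept={config.intercept}, effects="
                        f"{config.effects}; adjust the disease model")

    dos = np.vstack([
        np.asarray(kept[1]).reshape(config.n_cases, m),
        np.asarray(kept[0]).reshape(config.n_controls, m),
    ]) if config.n_cases + config.n_controls else np.empty((0, m))
    phenotype = np.r_[np.ones(config.n_cases, int),
                      np.zeros(config.n_controls, int)]

    severity = np.where(phenotype == 1, "mild", "none").astype(object)
    n_ms = int(round(config.severity_fraction * config.n_cases))
    if n_ms:
        pick = rng.choice(config.n_cases, size=n_ms, replace=False)
        severity[pick] = "moderate_severe"

    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos = np.where(mask, np.nan, dos)

    panel = config.panel
    return GenotypeDataset(
        sample_ids=[f"S{i:05d}" for i in range(len(phenotype))],
        snp_ids=panel.snp_ids,
        dosages=dos,
        counted_alleles=panel.table["counted_allele"].tolist(),
        other_alleles=panel.table["other_allele"].tolist(),
        phenotype=phenotype,
        severity=severity,
    )


def true_parameter_manifest(config: SimConfig) -> dict:
    """The generating truth of a simulation, for provenance files."""
    return {
        "seed": config.seed,
        "intercept": config.intercept,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "severity_fraction": config.severity_fraction,
        "missing_rate": config.missing_rate,
        "effects": {s: config.effects.get(s, 0.0) for s in config.panel.snp_ids},
        "ld_pairs": [list(p) for p in config.ld_pairs],
    }
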