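"""Per-SNP QC and log-additive logistic association.

The association model is logistic regression of case status on the 0/1/2
counted-allele dosage (log-additive coding): beta is the log-odds per allele
copy, the standard error comes from the observed information at the MLE, and
the p-value is the two-sided Wald normal tail of z = beta/se.  QC covers
minor-allele frequency, the exact conditional Hardy-Weinberg test, and
greedy LD pruning at a dosage-correlation threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

DEFAULT_LD_THRESHOLD = 0.2
DEFAULT_HWE_ALPHA = 0.05


class UndefinedValueError(ValueError):
    """Statistic undefined for the given data (all missing, zero variance)."""


@dataclass(frozen=True)
class AssociationResult:
    """Log-additive association of one SNP: log-odds per counted allele."""

    snp_id: str
    counted_allele: str
    beta: float
    se: float
    z: float
    p: float
    n_used: int
    converged: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def compute_maf(dosages: np.ndarray) -> tuple[float, float]:
    """Counted-allele frequency and MAF of one dosage column.

    Frequency is sum(d) / (2 * n_nonmissing); MAF folds it to [0, 0.5].
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedValueError("allele frequency undefined: all dosages missing")
    freq = d.sum() / (2.0 * d.size)
    return freq, min(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional HWE test p-value.

    Conditions on the observed minor-allele count: every heterozygote count
    of matching parity has probability proportional to the multinomial
    coefficient n!/(n_aa! n_Aa! n_AA!) times 2^n_het, and the p-value sums
    the probabilities of all configurations no more likely than the observed
    one.  Monomorphic samples have a single configuration, hence p = 1.
    """
    for c in (n_hom_minor, n_het, n_hom_major):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_minor + n_het + n_hom_major
    if n < 1:
        raise ValueError("need at least one individual")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # fold to the true minor allele

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log-probability up to the common normalising constant
    a = (n_minor - hets) // 2          # minor homozygotes
    c = n - a - hets                   # major homozygotes
    logw = (-_lgamma(a + 1) - _lgamma(hets + 1) - _lgamma(c + 1)
            + hets * math.log(2.0))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    if n_het not in hets:  # pragma: no cover - parity guaranteed by construction
        raise ValueError("observed heterozygote count incompatible with counts")
    p_obs = w[np.searchsorted(hets, n_het)]
    return float(min(1.0, w[w <= p_obs * (1 + 1e-12)].sum()))


def _lgamma(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over
    pairwise-complete individuals."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise UndefinedValueError("need >= 2 pairwise-complete individuals")
    if a.var() == 0 or b.var() == 0:
        raise UndefinedValueError("zero dosage variance; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_by_ld(dataset, pvalues: dict[str, float],
                threshold: float = DEFAULT_LD_THRESHOLD
                ) -> tuple[list[str], pd.DataFrame]:
    """Greedy LD pruning: visit SNPs by ascending association p-value and
    keep each one iff its r2 with every already-kept SNP is <= threshold.

    Returns the retained SNP ids (panel order) and a table of removals with
    the offending pair and r2.
    """
    order = sorted(dataset.snp_ids, key=lambda s: (pvalues.get(s, 1.0), s))
    kept: list[str] = []
    removed = []
    for snp in order:
        clash = None
        for other in kept:
            try:
                r2 = ld_r2(dataset.column(snp), dataset.column(other))
            except UndefinedValueError:
                continue
            if r2 > threshold:
                clash = (other, r2)
                break
        if clash is None:
            kept.append(snp)
        else:
            removed.append({"snp_id": snp, "removed_against": clash[0],
                            "r2": clash[1]})
    kept_panel_order = [s for s in dataset.snp_ids if s in set(kept)]
    removed_df = pd.DataFrame(removed, columns=["snp_id", "removed_against", "r2"])
    return kept_panel_order, removed_df


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
          ll_tol: float = 1e-10, step_tol: float = 1e-8):
    """Newton/IRLS maximum likelihood for logistic regression.

    Returns (beta, covariance, converged).  Convergence requires both a
    log-likelihood change below ``ll_tol`` and a step below ``step_tol``;
    step-halving guards against overshooting.  Quasi-separation shows up as
    diverging coefficients and is reported as non-convergence.
    """
    n, k = X.shape
    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    info = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving on likelihood decrease
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-14:
                break
            factor *= 0.5
        beta, eta = cand, eta_c
        dll, ll = ll_c - ll, ll_c
        if abs(dll) < ll_tol and np.max(np.abs(factor * step)) < step_tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 15:  # effectively separated
        converged = False
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return beta, cov, converged


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), stable in both tails
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_logadditive(dosages: np.ndarray, phenotype: np.ndarray,
                             snp_id: str = "", counted_allele: str = "",
                             covariates: np.ndarray | None = None
                             ) -> AssociationResult:
    """Fit logit P(y=1) = alpha + beta*g by maximum likelihood.

    Individuals with missing dosage are excluded (complete-case); ``n_used``
    reports the analysed count.  Non-convergence or separation yields
    ``converged=False`` with NaN se/z/p — never a silently wrong number.
    ``covariates`` is an optional (n, c) matrix adjusted for but not
    reported (defaults off; the study design matches rather than adjusts).
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    if y.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("association needs at least one case and one control")
    if np.var(g) == 0:
        raise ValueError(f"SNP {snp_id or '?'} monomorphic among non-missing "
                         "individuals; log-additive fit undefined")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[ok]
        cols.extend(cov.T if cov.ndim == 2 else [cov])
    X = np.column_stack(cols)
    beta, covm, converged = _irls(X, y)
    b = float(beta[1])
    se = float(np.sqrt(covm[1, 1])) if np.isfinite(covm[1, 1]) else np.nan
    if converged and np.isfinite(se) and se > 0:
        z = b / se
        p = float(2.0 * norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    else:
        converged = False
        z, p = np.nan, np.nan
    return AssociationResult(
        snp_id=snp_id, counted_allele=counted_allele, beta=b, se=se,
        z=float(z) if np.isfinite(se) else np.nan, p=p,
        n_used=int(y.size), converged=converged,
    )


def associate_all(dataset, covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Fit the log-additive model for every SNP column of the dataset."""
    y = dataset.require_phenotype()
    rows = []
    for j, snp in enumerate(dataset.snp_ids):
        res = fit_logistic_logadditive(
            dataset.dosages[:, j], y, snp_id=snp,
            counted_allele=dataset.counted_alleles[j], covariates=covariates)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(minor-hom, het, major-hom) counts with the counted allele as minor
    when its frequency is <= 0.5, folded otherwise."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n2 = int((d == 2).sum())
    n1 = int((d == 1).sum())
    n0 = int((d == 0).sum())
    freq = (2 * n2 + n1) / (2 * max(n0 + n1 + n2, 1))
    return (n2, n1, n0) if freq <= 0.5 else (n0, n1, n2)


def qc_report(dataset, hwe_on: str = "controls") -> pd.DataFrame:
    """Per-SNP MAF (controls and overall), HWE exact p and call rate.

    HWE is tested on controls by default (``hwe_on="controls"``), the
    standard QC practice for case/control panels; ``hwe_on="all"`` uses the
    combined sample.
    """
    if hwe_on not in ("controls", "all"):
        raise ValueError("hwe_on must be 'controls' or 'all'")
    y = dataset.phenotype
    rows = []
    for j, snp in enumerate(dataset.snp_ids):
        col = dataset.dosages[:, j]
        _, maf_all = compute_maf(col)
        if y is not None and (y == 0).any():
            _, maf_ctrl = compute_maf(col[y == 0])
            hwe_col = col[y == 0] if hwe_on == "controls" else col
        else:
            maf_ctrl = np.nan
            hwe_col = col
        hwe_p = hwe_exact_test(*genotype_counts(hwe_col))
        rows.append({
            "snp_id": snp,
            "maf_controls": maf_ctrl,
            "maf_all": maf_all,
            "hwe_p": hwe_p,
            "call_rate": float(np.mean(~np.isnan(col))),
        })
    return pd.DataFrame(rows)
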