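"""Weighted polygenic score and its association with disease.

The score is the weighted sum over panel SNPs of the individual's risk-
allele dosage: PGS_i = sum_j w_j * r_ij where r_ij = g_ij when the risk
allele is the counted allele and 2 - g_ij otherwise.  Disease association
is a logistic regression of case status on the standardized (per-SD) score;
the odds ratio is therefore per standard deviation of the PGS in the
analysed sample — a convention the outputs flag explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc_qc import _irls

STRATA = ("all_cases", "moderate_severe")


@dataclass(frozen=True)
class ScoreAssociation:
    """Odds ratio per SD of the PGS in one case stratum vs all controls."""

    stratum: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    scale: str = "per_sd_of_pgs"

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def compute_pgs(dataset, weight_set: pd.DataFrame,
                missing_policy: str = "mean_impute") -> pd.DataFrame:
    """Per-individual PGS under one weight set.

    ``mean_impute`` replaces a missing risk dosage with twice the control-
    sample risk-allele frequency (the dosage's expectation); ``skip_rescale``
    omits missing SNPs and rescales by total/used weight.  Every weight-set
    SNP must be present in the dataset — scores over silently shrunken
    panels are not comparable, so absence is a hard error.

    Returns a DataFrame with ``sample_id``, ``raw_score``, ``z_score``
    (standardized over the full sample), ``n_snps_used``, ``n_imputed``.
    """
    if missing_policy not in ("mean_impute", "skip_rescale"):
        raise ValueError("missing_policy must be mean_impute or skip_rescale")
    missing = [s for s in weight_set["snp_id"] if s not in dataset.snp_ids]
    if missing:
        raise ValueError(f"weight-set SNPs absent from dataset: {missing}")

    n = dataset.n_samples
    m = len(weight_set)
    risk_dos = np.empty((n, m))
    wvec = weight_set["weight"].to_numpy(float)
    ctrl = (dataset.phenotype == 0) if dataset.phenotype is not None else \
        np.ones(n, bool)
    ctrl_freqs = np.empty(m)
    for k, (_, row) in enumerate(weight_set.iterrows()):
        j = dataset.snp_ids.index(row["snp_id"])
        g = dataset.dosages[:, j]
        if row["risk_allele"] == dataset.counted_alleles[j]:
            r = g
        elif row["risk_allele"] == dataset.other_alleles[j]:
            r = 2.0 - g
        else:
            raise ValueError(
                f"{row['snp_id']}: risk allele {row['risk_allele']} matches "
                "neither stored allele")
        risk_dos[:, k] = r
        rc = r[ctrl]
        rc = rc[~np.isnan(rc)]
        ctrl_freqs[k] = rc.sum() / (2 * rc.size) if rc.size else np.nan

    miss = np.isnan(risk_dos)
    n_imputed = miss.sum(axis=1)
    n_used = m - n_imputed
    if missing_policy == "mean_impute":
        fill = np.broadcast_to(2.0 * ctrl_freqs, risk_dos.shape)
        filled = np.where(miss, fill, risk_dos)
        raw = filled @ wvec
    else:
        used_w = np.where(miss, 0.0, wvec).sum(axis=1)
        raw = np.nansum(risk_dos * wvec, axis=1)
        total_w = wvec.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(used_w > 0, raw * total_w / used_w, 0.0)

    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "raw_score": raw,
        "z_score": z,
        "n_snps_used": n_used,
        "n_imputed": n_imputed,
    })


def stratum_mask(dataset, stratum: str) -> np.ndarray:
    """Boolean mask selecting the analysis sample for a stratum: all
    controls plus either every case or only moderate-to-severe cases."""
    y = dataset.require_phenotype()
    if stratum == "all_cases":
        return np.ones(len(y), bool)
    if stratum == "moderate_severe":
        if dataset.severity is None:
            raise ValueError("dataset carries no severity labels")
        return (y == 0) | (dataset.severity == "moderate_severe")
    raise ValueError(f"unknown stratum {stratum!r}")


def score_association(raw_scores: np.ndarray, phenotype: np.ndarray,
                      stratum: str = "all_cases",
                      mask: np.ndarray | None = None) -> ScoreAssociation:
    """Logistic regression of case status on the per-SD standardized PGS.

    The score is re-standardized within the analysed sample (stratum cases
    plus all controls) so each stratum analysis is self-contained.
    """
    s = np.asarray(raw_scores, float)
    y = np.asarray(phenotype, int)
    if mask is not None:
        s, y = s[mask], y[mask]
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 cases and >= 2 controls in the stratum")
    sd = s.std()
    if sd == 0:
        raise ValueError("zero PGS variance; association undefined")
    z = (s - s.mean()) / sd
    X = np.column_stack([np.ones_like(z), z])
    beta, cov, converged = _irls(X, y.astype(float))
    if not converged:
        raise RuntimeError("score association fit did not converge")
    b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    wald = b / se
    return ScoreAssociation(
        stratum=stratum,
        or_per_sd=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        p=float(max(2.0 * norm.sf(abs(wald)), np.finfo(float).tiny)),
        n_cases=n1, n_controls=n0,
    )
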