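"""Per-SNP PGS weights: local betas or corrected external GWAS betas.

Two weighting designs are supported.  ``local`` takes the absolute value of
the in-sample log-additive beta.  ``gwas_corrected`` starts from external
GWAS summary statistics and, when the external meta-analysis contains a
cohort overlapping the analysis sample, removes that cohort's contribution
by inverting the fixed-effect inverse-variance pooling formula:

    beta_meta = sum(beta_k / se_k^2) / sum(1 / se_k^2)
    se_meta   = sqrt(1 / sum(1 / se_k^2))

so the leave-one-out effect is recovered by subtracting the removed study's
precision-weighted contribution.  SNPs absent from the summary statistics
can borrow the (corrected) beta of a high-LD proxy SNP, recorded with
``proxy:<rsid>`` provenance.  Risk alleles are, by default, oriented by the
sign of the *local* regression regardless of weight source.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import VariantPanel

#: Proxy substitutions used when external summary statistics lack a panel
#: SNP, paired positionally (absent SNP -> high-LD stand-in).
TAGC_PROXY_PAIRS = [
    ("rs13182402", "rs6861395"),
    ("rs41423247", "rs853180"),
    ("rs2781667", "rs2608897"),
    ("rs37973", "rs37972"),
    ("rs1049793", "rs11978239"),
    ("rs7140310", "rs17140310"),
    ("rs11000016", "rs11000000"),
]

DEFAULT_PROXY_R2 = 0.8


class StudyEffect(NamedTuple):
    """One study's (or a pooled) log-odds effect estimate."""

    beta: float
    se: float


class MetaInversionError(ValueError):
    """The removed study's weight is not strictly below the pooled weight."""


def meta_fixed_effect(effects: list[StudyEffect]) -> StudyEffect:
    """Fixed-effect inverse-variance pooled estimate."""
    if not effects:
        raise ValueError("meta-analysis needs at least one study")
    betas = np.array([e.beta for e in effects], dtype=float)
    ses = np.array([e.se for e in effects], dtype=float)
    if not (np.isfinite(ses).all() and (ses > 0).all()):
        raise ValueError("all study SEs must be finite and positive")
    w = 1.0 / ses**2
    return StudyEffect(float((w * betas).sum() / w.sum()),
                       float(np.sqrt(1.0 / w.sum())))


def remove_study_from_meta(meta: StudyEffect,
                           removed: StudyEffect) -> StudyEffect:
    """Invert fixed-effect pooling: the meta-estimate without one study.

    Requires the removed study's precision to be strictly below the pooled
    precision (equality would mean removing the only study).
    """
    w_meta = 1.0 / meta.se**2
    w_rm = 1.0 / removed.se**2
    if not w_rm < w_meta:
        raise MetaInversionError(
            "removed study's weight must be strictly less than the pooled "
            f"weight (1/se^2: removed {w_rm:.6g} vs meta {w_meta:.6g})")
    w_rest = w_meta - w_rm
    beta = (meta.beta * w_meta - removed.beta * w_rm) / w_rest
    return StudyEffect(float(beta), float(np.sqrt(1.0 / w_rest)))


def assign_risk_allele(beta: float, counted_allele: str,
                       other_allele: str) -> tuple[str, float]:
    """Orient a counted-allele beta into (risk_allele, non-negative weight).

    Positive beta: the counted allele is the risk allele.  Negative beta:
    the other allele is (risk dosage 2-g).  A beta of exactly zero keeps
    the counted allele with weight zero (documented tie rule).
    """
    if beta < 0:
        return other_allele, -float(beta)
    return counted_allele, float(beta)


WEIGHT_COLUMNS = ["snp_id", "risk_allele", "weight", "source", "beta_origin"]


def build_weight_set(panel: VariantPanel,
                     local_assoc: pd.DataFrame,
                     summary_stats: pd.DataFrame | None = None,
                     removed_cohort: pd.DataFrame | None = None,
                     proxy_map: list[tuple[str, str, float]] | None = None,
                     mode: str = "local",
                     proxy_threshold: float = DEFAULT_PROXY_R2,
                     orient_by: str = "local",
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Build the per-SNP weight table for one weighting design.

    ``local_assoc`` is the in-sample association table (columns ``snp_id``,
    ``beta``, ``converged``); it supplies weights in ``local`` mode and risk
    orientation in both modes (``orient_by="external"`` switches orientation
    to the corrected external sign instead).  ``removed_cohort`` holds the
    overlapping cohort's per-SNP beta/se for leave-one-out correction;
    ``proxy_map`` rows are ``(missing_snp, proxy_snp, r2)`` and a proxy is
    admissible only when ``r2 >= proxy_threshold``.

    Returns ``(weight_table, dropped_snp_ids)``; accounting always holds:
    ``len(panel) == len(weight_table) + len(dropped)``.
    """
    if mode not in ("local", "gwas_corrected"):
        raise ValueError("mode must be 'local' or 'gwas_corrected'")
    if orient_by not in ("local", "external"):
        raise ValueError("orient_by must be 'local' or 'external'")
    local = local_assoc.set_index("snp_id")
    missing_local = [s for s in panel.snp_ids if s not in local.index]
    if missing_local:
        raise ValueError(f"local association missing for: {missing_local}")
    if mode == "gwas_corrected" and summary_stats is None:
        raise ValueError("gwas_corrected mode requires summary statistics")

    ext = None
    if summary_stats is not None:
        ext = summary_stats.set_index("snp_id")
    rm = removed_cohort.set_index("snp_id") if removed_cohort is not None else None
    proxies = {m: (p, r2) for m, p, r2 in (proxy_map or [])}

    rows, dropped = [], []
    for _, prow in panel.table.iterrows():
        snp = prow.snp_id
        lbeta = float(local.loc[snp, "beta"])
        if not bool(local.loc[snp, "converged"]):
            raise ValueError(f"{snp}: local association did not converge; "
                             "cannot orient the risk allele")
        if mode == "local":
            risk, w = assign_risk_allele(lbeta, prow.counted_allele,
                                         prow.other_allele)
            rows.append({"snp_id": snp, "risk_allele": risk, "weight": w,
                         "source": "local", "beta_origin": lbeta})
            continue

        if snp in ext.index:
            beta_ext = _oriented_external_beta(ext.loc[snp], prow)
            beta_corr = _loo_correct(snp, beta_ext, float(ext.loc[snp, "se"]),
                                     rm, prow)
            source = "gwas_corrected"
        elif snp in proxies:
            proxy_id, r2 = proxies[snp]
            if r2 < proxy_threshold:
                dropped.append(snp)
                continue
            if proxy_id not in ext.index:
                dropped.append(snp)
                continue
            pp = _proxy_panel_row(panel, proxy_id, ext.loc[proxy_id])
            beta_ext = _oriented_external_beta(ext.loc[proxy_id], pp)
            beta_corr = _loo_correct(proxy_id, beta_ext,
                                     float(ext.loc[proxy_id, "se"]), rm, pp)
            source = f"proxy:{proxy_id}"
        else:
            dropped.append(snp)
            continue

        orient_beta = lbeta if orient_by == "local" else beta_corr
        risk, _ = assign_risk_allele(orient_beta, prow.counted_allele,
                                     prow.other_allele)
        rows.append({"snp_id": snp, "risk_allele": risk,
                     "weight": abs(beta_corr), "source": source,
                     "beta_origin": beta_corr})

    if not rows:
        raise ValueError("weight set is empty; no panel SNP had an "
                         "admissible weight")
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS), dropped


def _oriented_external_beta(ext_row: pd.Series, panel_row) -> float:
    """Sign-flip an external beta onto the panel's counted allele; literal
    allele match required in one orientation or the other."""
    ea, oa = ext_row["effect_allele"], ext_row["other_allele"]
    counted, other = panel_row.counted_allele, panel_row.other_allele
    if (ea, oa) == (counted, other):
        return float(ext_row["beta"])
    if (ea, oa) == (other, counted):
        return -float(ext_row["beta"])
    raise ValueError(
        f"{ext_row.name}: external alleles {ea}/{oa} do not match panel "
        f"{counted}/{other} in either orientation")


def _proxy_panel_row(panel: VariantPanel, proxy_id: str, ext_row: pd.Series):
    """Allele frame for a proxy SNP: from the panel when typed there, else
    taken from the summary statistics themselves (the proxy is then already
    in its own counted-allele frame)."""
    try:
        return panel.row(proxy_id)
    except KeyError:
        class _Row:
            counted_allele = ext_row["effect_allele"]
            other_allele = ext_row["other_allele"]
        return _Row()


def _loo_correct(snp: str, beta_ext: float, se_ext: float,
                 removed: pd.DataFrame | None, frame_row) -> float:
    """Leave-one-out correction when the removed cohort reports this SNP;
    otherwise the external value passes through unchanged.  The removed
    cohort's beta is first sign-oriented into the same allele frame."""
    if removed is None or snp not in removed.index:
        return beta_ext
    rrow = removed.loc[snp]
    if "effect_allele" in removed.columns:
        beta_rm = _oriented_external_beta(rrow, frame_row)
    else:
        beta_rm = float(rrow["beta"])
    loo = remove_study_from_meta(
        StudyEffect(beta_ext, se_ext),
        StudyEffect(beta_rm, float(rrow["se"])))
    return loo.beta
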