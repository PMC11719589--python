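"""ROC analysis of the polygenic score.

AUC is the Mann-Whitney probability that a random case outscores a random
control, ties counted one half — computed from midranks, which is exactly
the pairwise count.  The default confidence interval is DeLong's, from the
variance of case and control placement values (the convention of the pROC
package most case/control PGS reports rely on); a seeded stratified
bootstrap is retained as a cross-check.  The operating point maximizes the
Youden index J = sensitivity + specificity - 1, ties broken toward the
lower threshold (higher sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    ci_method: str
    operating_rule: str
    curve: pd.DataFrame = field(repr=False, compare=False, default=None)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("curve")
        return d


def _split(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes must be present")
    return s, y


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (ties counted 1/2) and the full ROC curve.

    The curve classifies ``score >= threshold`` as case, evaluated at every
    distinct score plus a sentinel above the maximum, so it starts at (0,0)
    and ends at (1,1) with both coordinates non-decreasing.
    """
    s, y = _split(scores, labels)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    r = rankdata(s)  # midranks: pairwise tie-halving, exactly
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thresholds = np.unique(s)[::-1]
    tpr = np.empty(thresholds.size + 1)
    fpr = np.empty(thresholds.size + 1)
    tpr[0] = fpr[0] = 0.0  # threshold above every score
    cases = np.sort(s[y == 1])
    ctrls = np.sort(s[y == 0])
    for i, t in enumerate(thresholds, start=1):
        tpr[i] = (cases.size - np.searchsorted(cases, t, side="left")) / n1
        fpr[i] = (ctrls.size - np.searchsorted(ctrls, t, side="left")) / n0
    curve = pd.DataFrame({
        "threshold": np.r_[np.inf, thresholds],
        "fpr": fpr,
        "tpr": tpr,
    })
    return float(auc), curve


def delong_variance(scores, labels) -> float:
    """Variance of the AUC estimate from case/control placement values."""
    s, y = _split(scores, labels)
    cases, ctrls = s[y == 1], s[y == 0]
    if cases.size < 2 or ctrls.size < 2:
        raise ValueError("DeLong variance needs >= 2 per class")
    order = np.sort(ctrls)
    v10 = (np.searchsorted(order, cases, "left")
           + np.searchsorted(order, cases, "right")) / (2.0 * ctrls.size)
    order = np.sort(cases)
    v01 = (np.searchsorted(order, ctrls, "left")
           + np.searchsorted(order, ctrls, "right")) / (2.0 * cases.size)
    # v01 here is P(case < control); flip to the AUC frame
    v01 = 1.0 - v01
    return float(np.var(v10, ddof=1) / cases.size
                 + np.var(v01, ddof=1) / ctrls.size)


def auc_ci(scores, labels, method: str = "delong", n_boot: int = 2000,
           seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """95% (by default) confidence interval for the AUC.

    ``delong``: normal interval from the DeLong variance, truncated to
    [0, 1].  ``bootstrap``: percentile interval over ``n_boot`` stratified
    resamples, seeded.  A degenerate variance at AUC 0 or 1 collapses the
    interval to the point with a warning.
    """
    s, y = _split(scores, labels)
    auc, _ = roc_auc(s, y)
    if method == "delong":
        var = delong_variance(s, y)
        if var == 0.0:
            warnings.warn("degenerate AUC variance; interval collapses to "
                          "the point estimate", stacklevel=2)
            return auc, auc
        zq = 1.959963984540054 if alpha == 0.05 else \
            float(_norm_ppf(1 - alpha / 2))
        half = zq * np.sqrt(var)
        return float(max(0.0, auc - half)), float(min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases, ctrls = s[y == 1], s[y == 0]
        n1, n0 = cases.size, ctrls.size
        aucs = np.empty(n_boot)
        yy = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        for b in range(n_boot):
            sb = np.r_[rng.choice(cases, n1), rng.choice(ctrls, n0)]
            aucs[b], _ = _auc_only(sb, yy, n1, n0)
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        if lo == hi:
            warnings.warn("degenerate bootstrap AUC distribution",
                          stacklevel=2)
        return float(lo), float(hi)
    raise ValueError("method must be 'delong' or 'bootstrap'")


def _auc_only(s, y, n1, n0):
    r = rankdata(s)
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0), None


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def operating_point(curve: pd.DataFrame, rule: str = "youden"
                    ) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) at the curve's operating point.

    ``youden`` maximizes J = TPR - FPR; among ties the lowest threshold
    (highest sensitivity) wins.
    """
    if rule != "youden":
        raise ValueError(f"unknown operating-point rule {rule!r}")
    j = curve["tpr"].to_numpy() - curve["fpr"].to_numpy()
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # lowest threshold tie-break
    return (float(curve["threshold"].iloc[best]),
            float(curve["tpr"].iloc[best]),
            float(1.0 - curve["fpr"].iloc[best]))


def roc_summary(scores, labels, ci_method: str = "delong",
                rule: str = "youden", seed: int = 0) -> RocSummary:
    """One-stop ROC evaluation: AUC, CI, Youden operating point, curve."""
    s, y = _split(scores, labels)
    auc, curve = roc_auc(s, y)
    lo, hi = auc_ci(s, y, method=ci_method, seed=seed)
    thr, sens, spec = operating_point(curve, rule=rule)
    return RocSummary(
        auc=auc, ci_low=lo, ci_high=hi, threshold=thr,
        sensitivity=sens, specificity=spec,
        n_cases=int(y.sum()), n_controls=int((y == 0).sum()),
        ci_method=ci_method, operating_rule=rule, curve=curve,
    )
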