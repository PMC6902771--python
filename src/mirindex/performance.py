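"""Diagnostic performance metrics with confidence intervals.

Proportions (sensitivity, specificity, accuracy) get Wald normal-approximation
95% intervals, p +/- 1.96*sqrt(p(1-p)/m), clipped to [0, 1]; Wilson intervals
are available behind a flag.  AUC is the Mann-Whitney statistic with a DeLong
variance interval, and AUC differences between models scored on the same
samples are tested with the paired DeLong test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

Z95 = 1.96


@dataclass
class DiagnosticPerformance:
    n_positive: int
    n_negative: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    ci: dict  # metric name -> (low, high)

    def summary_row(self) -> dict:
        out = {"n_positive": self.n_positive, "n_negative": self.n_negative}
        for name in ("sensitivity", "specificity", "accuracy", "auc"):
            value = getattr(self, name)
            if value is None:
                continue
            lo, hi = self.ci[name]
            out[name] = value
            out[f"{name}_ci"] = f"{lo:.2f}-{hi:.2f}"
        return out


def proportion_ci(p: float, m: int, method: str = "wald"):
    """95% CI for a proportion with denominator m, clipped to [0, 1]."""
    if m <= 0:
        raise ValueError("denominator must be positive")
    if method == "wald":
        half = Z95 * np.sqrt(p * (1.0 - p) / m)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "wilson":
        lo, hi = stats.binomtest(int(round(p * m)), m).proportion_ci(method="wilson")
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def confusion_metrics(calls, truths, ci_method: str = "wald") -> DiagnosticPerformance:
    """Sensitivity / specificity / accuracy (no AUC) from binary calls."""
    calls = np.asarray(calls, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if calls.shape != truths.shape:
        raise ValueError("calls and truths must align")
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative truth")
    tp = int((calls & truths).sum())
    tn = int((~calls & ~truths).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    acc = (tp + tn) / (n_pos + n_neg)
    ci = {
        "sensitivity": proportion_ci(sens, n_pos, ci_method),
        "specificity": proportion_ci(spec, n_neg, ci_method),
        "accuracy": proportion_ci(acc, n_pos + n_neg, ci_method),
    }
    return DiagnosticPerformance(
        n_positive=n_pos, n_negative=n_neg,
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=None, ci=ci,
    )


def _delong_components(scores, truths):
    """Placement values (structural components) of the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    pos = scores[truths]
    neg = scores[~truths]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes to compute AUC")
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per positive
    v01 = cmp.mean(axis=0)  # per negative
    auc = float(cmp.mean())
    return auc, v10, v01


def roc_auc(scores, truths):
    """Mann-Whitney AUC with a DeLong-variance 95% CI, clipped to [0, 1].

    Returns (auc, ci_low, ci_high).  Constant scores give AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC undefined, reporting 0.5", stacklevel=2)
        return 0.5, 0.0, 1.0
    auc, v10, v01 = _delong_components(scores, truths)
    n1, n0 = v10.size, v01.size
    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01, ddof=1) / n0
    half = Z95 * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def delong_test(scores_a, scores_b, truths) -> float:
    """Two-sided paired DeLong P value for the difference between two AUCs
    estimated from different scores on the same samples."""
    truths = np.asarray(truths, dtype=bool)
    auc_a, v10a, v01a = _delong_components(scores_a, truths)
    auc_b, v10b, v01b = _delong_components(scores_b, truths)
    n1, n0 = v10a.size, v01a.size
    var = 0.0
    if n1 > 1:
        var += np.var(v10a - v10b, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01a - v01b, ddof=1) / n0
    if var <= 0:
        warnings.warn("zero-variance AUC difference; P = 1", stacklevel=2)
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def youden_statistic(scores, truths, threshold: float) -> float:
    """J = sensitivity + specificity - 1 under the rule score >= threshold -> positive."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    calls = scores >= threshold
    n_pos = truths.sum()
    n_neg = (~truths).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes")
    sens = (calls & truths).sum() / n_pos
    spec = (~calls & ~truths).sum() / n_neg
    return float(sens + spec - 1.0)


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints of adjacent distinct scores, plus sentinels below/above all scores."""
    u = np.unique(np.asarray(scores, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def best_youden_threshold(scores, truths):
    """(threshold, J) maximizing Youden's J; ties go to the smallest threshold."""
    best_t, best_j = None, -np.inf
    for t in candidate_thresholds(scores):
        j = youden_statistic(scores, truths, t)
        if j > best_j + 1e-15:
            best_t, best_j = float(t), j
    return best_t, best_j
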