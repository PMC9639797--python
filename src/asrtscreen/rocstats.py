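"""ROC inference: AUC, DeLong variance/CI/tests, Youden operating point, power.

The AUC is the Mann-Whitney probability that a randomly chosen positive
scores above a randomly chosen negative (ties counted 1/2).  DeLong's
structural-component decomposition provides a nonparametric variance
estimate, enabling Wald confidence intervals, tests against chance, and
paired tests between two correlated AUCs measured on the same subjects.

The Youden operating point maximizes J = sensitivity + specificity - 1 over
score thresholds; ties in J are broken toward higher specificity (fewer
false positives, the conservative choice for population screening).

``auc_power`` computes normal-approximation power for detecting an AUC above
chance with the Hanley-McNeil exponential-model variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "ThresholdMetrics",
    "auc",
    "delong_ci",
    "delong_test_paired",
    "youden_metrics",
    "cohen_kappa",
    "auc_power",
    "roc_points",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    level: float
    z: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    kappa: float


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney AUC estimate; ties between classes count 1/2."""
    pos, neg = _split(scores, labels)
    # Midrank formulation: AUC = (R_pos - m(m+1)/2) / (m n)
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10 (per positive) and V01 (per negative) via midranks."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = stats.rankdata(all_scores)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    a = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01, a


def delong_ci(scores, labels, level: float = 0.95) -> ROCResult:
    """DeLong variance with a Wald confidence interval and test against 0.5.

    A zero-variance estimate (e.g. perfect separation) collapses the CI to a
    point and is flagged ``degenerate``; by convention z = 0, p = 1 there.
    """
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("delong_ci requires at least 2 observations per class")
    v10, v01, a = _structural_components(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    se = float(np.sqrt(var))
    q = stats.norm.ppf(0.5 + level / 2)
    if se == 0.0:
        return ROCResult(a, 0.0, a, a, level, 0.0, 1.0, degenerate=True)
    z = (a - 0.5) / se
    p = 2 * stats.norm.sf(abs(z))
    lo = max(0.0, a - q * se)
    hi = min(1.0, a + q * se)
    return ROCResult(a, se, float(lo), float(hi), level, float(z), float(p))


def delong_test_paired(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for a difference between correlated AUCs.

    Both score vectors must be measured on the same subjects (same labels).
    Returns (z, p); a degenerate zero-variance difference gives (0, 1).
    """
    labels = np.asarray(labels)
    pos_mask = labels == 1
    neg_mask = labels == 0
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise ValueError("paired test requires equal-length scores and labels")
    va10, va01, auc_a = _structural_components(sa[pos_mask], sa[neg_mask])
    vb10, vb01, auc_b = _structural_components(sb[pos_mask], sb[neg_mask])
    m, n = int(pos_mask.sum()), int(neg_mask.sum())
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def cohen_kappa(tp: float, fp: float, fn: float, tn: float) -> float:
    """Chance-corrected agreement from a 2x2 confusion table (counts may be expectations)."""
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    po = (tp + tn) / total
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    if pe == 1.0:
        return 0.0
    return float((po - pe) / (1 - pe))


def youden_metrics(scores, labels) -> ThresholdMetrics:
    """Operating point maximizing Youden's J; predict positive when score > tau.

    Candidate thresholds are midpoints between adjacent distinct scores plus
    sentinels below/above all scores.  Ties in J resolve to the threshold
    with higher specificity.
    """
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2 if len(distinct) > 1 else np.array([])
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    best: ThresholdMetrics | None = None
    m, n = len(pos), len(neg)
    for tau in candidates:
        sn = float((pos > tau).sum() / m)
        sp = float((neg <= tau).sum() / n)
        j = sn + sp - 1
        if best is None or j > best.youden_j + 1e-12 or (
            abs(j - best.youden_j) <= 1e-12 and sp > best.specificity
        ):
            tp, fn = sn * m, (1 - sn) * m
            tn, fp = sp * n, (1 - sp) * n
            best = ThresholdMetrics(
                threshold=float(tau),
                sensitivity=sn,
                specificity=sp,
                youden_j=float(j),
                kappa=cohen_kappa(tp, fp, fn, tn),
            )
    assert best is not None
    return best


def roc_points(scores, labels) -> np.ndarray:
    """(1 - specificity, sensitivity) pairs over all thresholds, for plotting."""
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))
    pts = [(1.0, 1.0)]
    for tau in thresholds:
        pts.append((float((neg > tau).mean()), float((pos > tau).mean())))
    pts.append((0.0, 0.0))
    return np.array(sorted(set(pts)))


def _hanley_mcneil_var(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    return (
        a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)
    ) / (n_pos * n_neg)


def auc_power(n_pos: int, n_neg: int, auc_alt: float, alpha: float = 0.05) -> float:
    """Power to detect AUC = ``auc_alt`` against the chance null AUC = 0.5.

    Two-sided normal-approximation test with Hanley-McNeil exponential-model
    variances under the null and the alternative.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 subjects per class")
    if not 0.5 < auc_alt < 1:
        raise ValueError("auc_alt must lie strictly between 0.5 and 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sd0 = np.sqrt(_hanley_mcneil_var(0.5, n_pos, n_neg))
    sd1 = np.sqrt(_hanley_mcneil_var(auc_alt, n_pos, n_neg))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    # Power mass on the far side of the null is negligible; keep the
    # dominant one-sided term plus the symmetric correction.
    upper = stats.norm.cdf((auc_alt - 0.5 - z_crit * sd0) / sd1)
    lower = stats.norm.cdf((0.5 - auc_alt - z_crit * sd0) / sd1)
    return float(upper + lower)
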