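"""ROC/AUC evaluation of single-transcript markers.

AUC is the Mann-Whitney U statistic with half-credit for ties, computed on
log2 expression scores.  Automatic orientation guarantees AUC >= 0.5 (an
``oriented`` flag records when the direction was flipped, i.e. when lower
expression marks the cancer group).  Confidence intervals come from a
stratified percentile bootstrap (default 400 resamples, adaptively reduced
for very small classes) or from DeLong's structural-component variance.
Robustness can be probed with repeated stratified K-fold cross-validation
pooling out-of-fold scores.  A point estimate above 0.8 is flagged as
strong discrimination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

STRONG_AUC = 0.8
MIN_CLASS_FOR_CI = 2
BOOT_FLOOR = 50


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str          # bootstrap | delong | cv | none
    n_pos: int
    n_neg: int
    oriented: bool = False
    strong: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.strong = bool(self.auc > STRONG_AUC)


def _classes(scores, labels, pos_label) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == pos_label]
    neg = s[y != pos_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_points(scores, labels, pos_label=1) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs with a threshold at every distinct score, running
    from (0, 0) to (1, 1); tied scores share one threshold."""
    _classes(scores, labels, pos_label)
    y = (np.asarray(labels) == pos_label).astype(int)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, float),
                            drop_intermediate=False)
    pts = list(dict.fromkeys(zip(fpr.tolist(), tpr.tolist())))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def _auc_raw(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with tie half-credit."""
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    n1, n2 = len(pos), len(neg)
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def auc(scores, labels, pos_label=1, auto_orient: bool = True) -> ROCResult:
    """Point-estimate AUC with automatic orientation (flip if < 0.5)."""
    pos, neg = _classes(scores, labels, pos_label)
    a = _auc_raw(pos, neg)
    oriented = False
    if auto_orient and a < 0.5:
        a = 1.0 - a
        oriented = True
    return ROCResult(auc=a, ci_low=a, ci_high=a, ci_method="none",
                     n_pos=len(pos), n_neg=len(neg), oriented=oriented)


def _adaptive_n_boot(n_boot: int, n_pos: int, n_neg: int) -> int:
    """Cap the resample count when a class is very small: bound by that
    class's number of distinct bootstrap resamples (the multiset
    coefficient C(2n-1, n)), with a floor of 50."""
    distinct = min(math.comb(2 * n_pos - 1, n_pos), math.comb(2 * n_neg - 1, n_neg))
    return max(BOOT_FLOOR, min(n_boot, distinct))


def auc_ci_bootstrap(scores, labels, pos_label=1, n_boot: int = 400,
                     seed: int | None = None,
                     auto_orient: bool = True) -> ROCResult:
    """Stratified percentile-bootstrap 95% CI for the AUC.

    With fewer than 2 members in either class no meaningful interval
    exists: the point estimate is returned with ci = [0, 1] and
    ``ci_method='none'`` (logged).
    """
    point = auc(scores, labels, pos_label, auto_orient=auto_orient)
    pos, neg = _classes(scores, labels, pos_label)
    if len(pos) < MIN_CLASS_FOR_CI or len(neg) < MIN_CLASS_FOR_CI:
        logger.warning("bootstrap CI refused: class sizes %d/%d below %d; "
                       "reporting [0, 1]", len(pos), len(neg), MIN_CLASS_FOR_CI)
        return ROCResult(auc=point.auc, ci_low=0.0, ci_high=1.0,
                         ci_method="none", n_pos=len(pos), n_neg=len(neg),
                         oriented=point.oriented)
    n_eff = _adaptive_n_boot(n_boot, len(pos), len(neg))
    if n_eff != n_boot:
        logger.info("bootstrap resamples adaptively set to %d (requested %d)",
                    n_eff, n_boot)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_eff)
    n_skipped = 0
    for b in range(n_eff):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        a = _auc_raw(bp, bn)
        if point.oriented:
            a = 1.0 - a
        reps[b] = a
    reps = reps[np.isfinite(reps)]
    if n_skipped:
        logger.info("bootstrap: skipped %d degenerate replicates", n_skipped)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ROCResult(auc=point.auc, ci_low=float(lo), ci_high=float(hi),
                     ci_method="bootstrap", n_pos=len(pos), n_neg=len(neg),
                     oriented=point.oriented)


def delong_variance(scores, labels, pos_label=1) -> float:
    """DeLong structural-component variance of the (unoriented) AUC."""
    pos, neg = _classes(scores, labels, pos_label)
    m, n = len(pos), len(neg)
    # placement values: V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci_delong(scores, labels, pos_label=1,
                  auto_orient: bool = True) -> ROCResult:
    """DeLong 95% Wald CI for the AUC, clipped to [0, 1].

    Perfect separation gives zero variance; the CI collapses to the point
    estimate and the result is flagged degenerate.
    """
    pos, neg = _classes(scores, labels, pos_label)
    if len(pos) < MIN_CLASS_FOR_CI or len(neg) < MIN_CLASS_FOR_CI:
        raise ValueError("DeLong CI needs >= 2 members per class")
    point = auc(scores, labels, pos_label, auto_orient=auto_orient)
    var = delong_variance(scores, labels, pos_label)
    if var <= 0:
        logger.warning("DeLong: zero variance (perfect separation); CI "
                       "collapses to the point estimate")
        return ROCResult(auc=point.auc, ci_low=point.auc, ci_high=point.auc,
                         ci_method="delong", n_pos=len(pos), n_neg=len(neg),
                         oriented=point.oriented, degenerate=True)
    se = math.sqrt(var)
    lo = max(0.0, point.auc - 1.959963984540054 * se)
    hi = min(1.0, point.auc + 1.959963984540054 * se)
    return ROCResult(auc=point.auc, ci_low=lo, ci_high=hi, ci_method="delong",
                     n_pos=len(pos), n_neg=len(neg), oriented=point.oriented)


def cv_roc(scores, labels, pos_label=1, k: int = 5, repeats: int = 10,
           seed: int | None = None, auto_orient: bool = True) -> ROCResult:
    """Repeated stratified K-fold AUC, pooling out-of-fold scores.

    Each repeat pools its out-of-fold scores into one ROC; the result is
    the mean AUC over repeats with a percentile interval across repeats.
    K is clipped to the smaller class size (logged) and to the 2-5 range.
    """
    if not 2 <= k <= 5:
        raise ValueError("k must be in [2, 5]")
    if not 1 <= repeats <= 10:
        raise ValueError("repeats must be in [1, 10]")
    s = np.asarray(scores, float)
    y = (np.asarray(labels) == pos_label).astype(int)
    smallest = min(int(y.sum()), int((1 - y).sum()))
    if smallest < k:
        logger.info("cv_roc: k reduced from %d to class size %d", k, smallest)
        k = smallest
    if k < 2:
        raise ValueError("each class needs >= 2 members for cross-validation")
    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        oof_scores = np.empty_like(s)
        for _, test_idx in skf.split(s.reshape(-1, 1), y):
            # single-marker score: the out-of-fold prediction is the score
            oof_scores[test_idx] = s[test_idx]
        per_repeat.append(auc(oof_scores, y, pos_label=1,
                              auto_orient=auto_orient).auc)
    per_repeat = np.asarray(per_repeat)
    lo, hi = np.percentile(per_repeat, [2.5, 97.5])
    point = auc(s, y, pos_label=1, auto_orient=auto_orient)
    return ROCResult(auc=float(per_repeat.mean()), ci_low=float(lo),
                     ci_high=float(hi), ci_method="cv",
                     n_pos=int(y.sum()), n_neg=int((1 - y).sum()),
                     oriented=point.oriented)
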