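"""Evaluation statistics for binary classifiers.

AUC is the Mann-Whitney statistic (ties count one half).  Confidence
intervals are percentile bootstrap with class-stratified case resampling
(B = 1000 by default).  Two comparison tests are provided, matching how the
cohorts relate: an unpaired DeLong test for AUCs of independent cohorts, and
a paired bootstrap difference test for two models scored on the same cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger("petmip.evalstats")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Point estimates with bootstrap 95% CIs for one prediction set."""

    auc: float
    auc_ci: tuple[float, float]
    mcc: float
    mcc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n: int
    threshold: float
    seed: int

    def to_json_dict(self) -> dict:
        return asdict(self)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and the same length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0 or 1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Computed from midranks, which is algebraically identical to counting all
    positive-negative pairs.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Predicted positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive cases")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no negative cases")
    return c.tn / (c.tn + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom2 = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom2 == 0:
        logger.info("mcc: zero denominator factor, returning 0 by convention")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom2))


def _stratified_resample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        idx.append(rng.choice(cls_idx, size=cls_idx.size, replace=True))
    return np.concatenate(idx)


def bootstrap_ci(
    metric,
    scores,
    labels,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap CI for metric(scores, labels).

    Resampling is case-level with replacement, stratified by class so every
    resample contains both classes; with ``stratified=False`` degenerate
    resamples are redrawn (and logged).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    n = labels.size
    for b in range(B):
        if stratified:
            idx = _stratified_resample(labels, rng)
        else:
            idx = rng.integers(0, n, size=n)
            redraws = 0
            while labels[idx].min() == labels[idx].max():
                idx = rng.integers(0, n, size=n)
                redraws += 1
            if redraws:
                logger.info("bootstrap_ci: redrew %d degenerate resamples", redraws)
        stats[b] = metric(scores[idx], labels[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def metric_report(
    scores,
    labels,
    threshold: float = 0.5,
    B: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """AUC / MCC / sensitivity / specificity with bootstrap 95% CIs."""
    scores, labels = _check_scores_labels(scores, labels)

    def sens_m(s, y):
        return sensitivity(confusion_at_threshold(s, y, threshold))

    def spec_m(s, y):
        return specificity(confusion_at_threshold(s, y, threshold))

    def mcc_m(s, y):
        return mcc(confusion_at_threshold(s, y, threshold))

    c = confusion_at_threshold(scores, labels, threshold)
    return MetricReport(
        auc=roc_auc(scores, labels),
        auc_ci=bootstrap_ci(roc_auc, scores, labels, B=B, seed=seed),
        mcc=mcc(c),
        mcc_ci=bootstrap_ci(mcc_m, scores, labels, B=B, seed=seed + 1),
        sensitivity=sensitivity(c),
        sensitivity_ci=bootstrap_ci(sens_m, scores, labels, B=B, seed=seed + 2),
        specificity=specificity(c),
        specificity_ci=bootstrap_ci(spec_m, scores, labels, B=B, seed=seed + 3),
        n=labels.size,
        threshold=threshold,
        seed=seed,
    )


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing sensitivity + specificity - 1."""
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, thresholds = _roc_curve(scores, labels)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x_i, y_j): 1 if pos > neg, 0.5 if equal, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(np.float64)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> float:
    """var(AUC) = S10/m + S01/n from the DeLong structural components."""
    scores, labels = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test_unpaired(
    scores_a, labels_a, scores_b, labels_b
) -> tuple[float, float, float, float]:
    """DeLong test for AUCs of two independent cohorts.

    Returns (auc_a, auc_b, z, two-sided p).  The variance of each AUC comes
    from its own structural components; independence means the covariance
    term vanishes.
    """
    sa, ya = _check_scores_labels(scores_a, labels_a)
    sb, yb = _check_scores_labels(scores_b, labels_b)
    auc_a = roc_auc(sa, ya)
    auc_b = roc_auc(sb, yb)
    var_a = delong_auc_variance(sa, ya)
    var_b = delong_auc_variance(sb, yb)
    se = np.sqrt(var_a + var_b)
    if se == 0:
        raise ValueError("degenerate DeLong variance (all structural components equal)")
    z = (auc_a - auc_b) / se
    p = 2.0 * norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def bootstrap_auc_diff_test(
    scores_1,
    scores_2,
    labels,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float], float]:
    """Paired bootstrap test for the AUC difference of two models on the same cases.

    Cases are resampled jointly (class-stratified); returns (delta_auc,
    percentile CI, two-sided p) with p = 2 * min(P(delta* <= 0), P(delta* >= 0))
    capped at 1.
    """
    s1 = np.asarray(scores_1, dtype=np.float64)
    s2 = np.asarray(scores_2, dtype=np.float64)
    if s1.shape != s2.shape:
        raise ValueError("paired score vectors must have the same length")
    _, y = _check_scores_labels(s1, labels)
    delta = roc_auc(s1, y) - roc_auc(s2, y)
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    for b in range(B):
        idx = _stratified_resample(y, rng)
        deltas[b] = roc_auc(s1[idx], y[idx]) - roc_auc(s2[idx], y[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = 2.0 * min(np.mean(deltas <= 0.0), np.mean(deltas >= 0.0))
    return float(delta), (float(lo), float(hi)), float(min(p, 1.0))


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    from sklearn.metrics import roc_curve as _sk_roc

    return _sk_roc(labels, scores, drop_intermediate=False)


def roc_points(scores, labels) -> np.ndarray:
    """Ordered (FPR, TPR) pairs from (0,0) to (1,1); trapezoidal area = AUC."""
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, _ = _roc_curve(scores, labels)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], (0.0, 0.0)):
        pts = np.vstack([(0.0, 0.0), pts])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, (1.0, 1.0)])
    return pts
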