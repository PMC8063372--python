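"""ROC analysis of the structure-based distance scores.

Pain-related sites tend to minimise their distance scores, so the
classifier's orientation is low-score-predicts-pain.  The empirical ROC
curve is swept over the midpoints of sorted unique scores (plus the two
infinite endpoints); the AUC is the trapezoid-rule area, which for this
construction equals the pairwise concordance (Mann-Whitney) statistic with
ties counted one half.  The reported optimal threshold maximises Youden's
J = sensitivity + specificity - 1, ties broken toward higher specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RocResult:
    score_name: str
    n_pos: int
    n_neg: int
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    low_predicts_positive: bool = True


@dataclass
class OptimalThreshold:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    tp: int
    fn: int
    tn: int
    fp: int


def roc_curve(
    scores,
    labels,
    positive_label: str = "pain",
    low_predicts_positive: bool = True,
    score_name: str = "score",
) -> RocResult:
    """Empirical ROC of a score against binary labels.

    With the default orientation a site is predicted positive (pain) when
    its score is <= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    s = scores if low_predicts_positive else -scores
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # predicted positive: s <= threshold
    sens = np.array([(s[pos] <= th).mean() for th in thresholds])
    spec = np.array([(s[~pos] > th).mean() for th in thresholds])
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    if not low_predicts_positive:
        thresholds = -thresholds
    return RocResult(
        score_name=score_name,
        n_pos=n_pos,
        n_neg=n_neg,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        low_predicts_positive=low_predicts_positive,
    )


def concordance_auc(scores, labels, positive_label: str = "pain", low_predicts_positive: bool = True) -> float:
    """Brute-force pairwise-concordance (Mann-Whitney) AUC, ties counted 1/2.

    Kept as the closed-form counterpart of the trapezoid AUC; the two must
    agree to numerical precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    s = scores if low_predicts_positive else -scores
    p = s[labels == positive_label]
    n = s[labels != positive_label]
    wins = (p[:, None] < n[None, :]).sum() + 0.5 * (p[:, None] == n[None, :]).sum()
    return float(wins / (len(p) * len(n)))


def optimal_threshold(roc: RocResult, rule: str = "youden") -> OptimalThreshold:
    """Optimal operating point of the ROC curve.

    Youden's J = sens + spec - 1 is maximised; ties go to the point with
    higher specificity, then to the smaller threshold (deterministic).
    """
    if rule != "youden":
        raise ValueError(f"unknown threshold rule {rule!r}")
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if j[i] > j[best] + 1e-12:
            best = i
        elif abs(j[i] - j[best]) <= 1e-12:
            if roc.specificity[i] > roc.specificity[best] + 1e-12:
                best = i
            elif (
                abs(roc.specificity[i] - roc.specificity[best]) <= 1e-12
                and roc.thresholds[i] < roc.thresholds[best]
            ):
                best = i
    th = float(roc.thresholds[best])
    sens = float(roc.sensitivity[best])
    spec = float(roc.specificity[best])
    tp = int(round(sens * roc.n_pos))
    tn = int(round(spec * roc.n_neg))
    return OptimalThreshold(
        threshold=th,
        sensitivity=sens,
        specificity=spec,
        youden_j=float(j[best]),
        tp=tp,
        fn=roc.n_pos - tp,
        tn=tn,
        fp=roc.n_neg - tn,
    )
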