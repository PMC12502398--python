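"""Diagnostic evaluation statistics.

Sensitivity/specificity carry Agresti-Coull binomial intervals; ROC AUC
follows the Mann-Whitney identity (ties get half credit) with
equi-tailed percentile intervals from stratified nonparametric
bootstrapping (default R = 100); three-class performance is summarized
by one-vs-rest AUCs, their unweighted mean (macro-AUC) and the AUC of
the pooled sample x class binary expansion (micro-AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "BinaryMetrics",
    "MulticlassAucReport",
    "agresti_coull_interval",
    "binary_metrics",
    "roc_auc",
    "bootstrap_auc_ci",
    "multiclass_auc",
]


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    specificity: float
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class MulticlassAucReport:
    auc_per_class: dict[str, float]
    macro_auc: float
    micro_auc: float
    ci_per_class: dict[str, tuple[float, float]] | None = None
    ci_micro: tuple[float, float] | None = None


def agresti_coull_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Adjusted-count binomial confidence interval, truncated to [0, 1].

    With z the two-sided normal quantile: n~ = n + z^2,
    p~ = (x + z^2/2) / n~, half-width z * sqrt(p~ (1 - p~) / n~).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    if not (0 < conf < 1):
        raise ValueError(f"conf must be in (0, 1); got {conf}")
    z = stats.norm.ppf(0.5 + conf / 2)
    n_tilde = n + z**2
    p_tilde = (x + z**2 / 2) / n_tilde
    half = z * np.sqrt(p_tilde * (1 - p_tilde) / n_tilde)
    return (max(0.0, float(p_tilde - half)), min(1.0, float(p_tilde + half)))


def binary_metrics(predicted, truth, positive, conf: float = 0.95) -> BinaryMetrics:
    """Sensitivity (TPR) and specificity (TNR) of hard class calls, with
    Agresti-Coull intervals at ``conf``."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must align")
    pos = truth == positive
    if not pos.any():
        raise ValueError(f"positive class {positive!r} absent from truth")
    if pos.all():
        raise ValueError("truth contains only the positive class; specificity undefined")
    pred_pos = predicted == positive
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    return BinaryMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ci_sens=agresti_coull_interval(tp, tp + fn, conf),
        ci_spec=agresti_coull_interval(tn, tn + fp, conf),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def roc_auc(scores, truth) -> float:
    """AUC via the rank (Mann-Whitney) statistic: P(score+ > score-) with
    half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("both truth classes must be present")
    return float(roc_auc_score(truth, scores))


def _rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Midrank Mann-Whitney AUC; equal to :func:`roc_auc`, O(n log n)
    with minimal overhead for the bootstrap inner loop."""
    ranks = stats.rankdata(scores)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc_ci(
    scores, truth, R: int = 100, conf: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Equi-tailed percentile interval of the AUC over R nonparametric
    bootstrap resamples, stratified within each truth class so every
    resample retains both classes."""
    if R < 1:
        raise ValueError(f"R must be >= 1; got {R}")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos_idx = np.flatnonzero(truth)
    neg_idx = np.flatnonzero(~truth)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both truth classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(R)
    for r in range(R):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([bp, bn])
        aucs[r] = _rank_auc(scores[idx], truth[idx])
    lo, hi = np.quantile(aucs, [(1 - conf) / 2, 0.5 + conf / 2])
    return (float(lo), float(hi))


def multiclass_auc(
    probs: pd.DataFrame,
    truth,
    bootstrap: bool = False,
    R: int = 100,
    conf: float = 0.95,
    seed: int = 0,
) -> MulticlassAucReport:
    """One-vs-rest, macro and micro AUC for a probability table.

    ``probs`` has one column per class (values need not be normalized for
    the per-class AUCs, but should be the class-probability columns of a
    classifier); ``truth`` holds the class labels.  Macro-AUC is the
    unweighted mean of per-class AUCs; micro-AUC pools every
    (sample, class) pair with binary membership labels.
    """
    truth = np.asarray(truth)
    classes = list(probs.columns)
    missing = set(truth) - set(classes)
    if missing:
        raise ValueError(f"probability column(s) missing for class(es): {sorted(missing)}")
    for cls in classes:
        if not (truth == cls).any():
            raise ValueError(f"class {cls!r} absent from truth")

    per_class: dict[str, float] = {}
    ci_per_class: dict[str, tuple[float, float]] = {}
    pooled_scores = []
    pooled_truth = []
    for cls in classes:
        y = truth == cls
        s = probs[cls].to_numpy(dtype=float)
        per_class[cls] = roc_auc(s, y)
        if bootstrap:
            ci_per_class[cls] = bootstrap_auc_ci(s, y, R=R, conf=conf, seed=seed)
        pooled_scores.append(s)
        pooled_truth.append(y)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_truth = np.concatenate(pooled_truth)
    micro = roc_auc(pooled_scores, pooled_truth)
    return MulticlassAucReport(
        auc_per_class=per_class,
        macro_auc=float(np.mean(list(per_class.values()))),
        micro_auc=micro,
        ci_per_class=ci_per_class or None,
        ci_micro=bootstrap_auc_ci(pooled_scores, pooled_truth, R=R, conf=conf, seed=seed)
        if bootstrap
        else None,
    )
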