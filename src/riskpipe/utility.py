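"""Diagnostic-accuracy metrics and the cross-validated clinical utility.

The clinical utility maximized by the pipeline optimizer is the mean of the
trapezoidal area under the precision-recall curve (AUC-PR) and the average
precision (AP).  Both emphasise the positive predictive value of referral
decisions in an imbalanced cohort, where AUC-ROC can be deceptively high.

Conventions
-----------
* Tied scores are grouped into a single threshold; the PR curve has one point
  per distinct threshold, thresholds descending.
* For AUC-PR the curve is reduced to one (recall, max precision) point per
  distinct recall and anchored at (recall 0, first precision), which makes the
  trapezoid well-defined and monotone in recall.
* A classification at cutoff ``c`` predicts positive when ``score >= c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ScoredOutcomes:
    """Binary labels paired with risk scores in [0, 1]."""

    y: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=int)
        s = np.asarray(self.s, dtype=float)
        if y.shape != s.shape or y.ndim != 1:
            raise ValueError("y and s must be 1-D arrays of equal length")
        if y.size < 2:
            raise ValueError("need at least 2 observations")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("labels must be binary")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "s", s)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class UtilityValue:
    """Cross-validated clinical utility with its two components."""

    utility: float
    auc_pr: float
    average_precision: float
    per_fold: tuple = field(default_factory=tuple)
    n_folds: int = 0
    sd: float = float("nan")


def _threshold_counts(scored: ScoredOutcomes):
    """Cumulative TP/FP per distinct descending threshold (ties grouped)."""
    order = np.argsort(-scored.s, kind="mergesort")
    s_sorted = scored.s[order]
    y_sorted = scored.y[order]
    # last index of each tie-group of scores
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(1 - y_sorted)[idx]
    return s_sorted[idx], tp, fp


def pr_curve(scored: ScoredOutcomes) -> list[tuple[float, float]]:
    """Precision-recall points, one per distinct threshold, thresholds descending.

    Raises
    ------
    ValueError
        If there is no positive label (recall undefined).
    """
    if scored.n_pos == 0:
        raise ValueError("undefined recall: no positive labels")
    _, tp, fp = _threshold_counts(scored)
    recall = tp / scored.n_pos
    precision = tp / (tp + fp)
    return list(zip(recall.tolist(), precision.tolist()))


def auc_pr(scored: ScoredOutcomes) -> float:
    """Trapezoidal area under the precision-recall curve.

    The curve keeps the maximum precision per distinct recall and is anchored
    at (0, first precision) before integrating over recall.
    """
    pts = pr_curve(scored)
    by_recall: dict[float, float] = {}
    for r, p in pts:
        if r not in by_recall or p > by_recall[r]:
            by_recall[r] = p
    recalls = sorted(by_recall)
    precs = [by_recall[r] for r in recalls]
    if recalls[0] > 0.0:
        recalls = [0.0] + recalls
        precs = [precs[0]] + precs
    return float(np.trapezoid(precs, recalls))


def average_precision(scored: ScoredOutcomes) -> float:
    """Recall-increment-weighted mean of precisions over descending thresholds."""
    pts = pr_curve(scored)
    ap = 0.0
    prev_r = 0.0
    for r, p in pts:
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def clinical_utility(scored: ScoredOutcomes) -> float:
    """Mean of AUC-PR and average precision — the optimizer's objective."""
    return 0.5 * (auc_pr(scored) + average_precision(scored))


def auc_roc(scored: ScoredOutcomes) -> float:
    if scored.n_pos in (0, scored.y.size):
        raise ValueError("AUC-ROC requires both classes")
    return float(roc_auc_score(scored.y, scored.s))


def youden_j(scored: ScoredOutcomes) -> tuple[float, float]:
    """Maximum of sensitivity + specificity − 1 over cutoffs, with its cutoff.

    Ties are broken toward the lowest cutoff (favours sensitivity).
    """
    n_pos = scored.n_pos
    n_neg = scored.y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden's J requires both classes")
    thr, tp, fp = _threshold_counts(scored)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    # scan from the lowest cutoff so ties resolve to the lowest
    best = int(np.argmax(j[::-1]))
    k = j.size - 1 - best
    return float(j[k]), float(thr[k])


def confusion_at_cutoff(scored: ScoredOutcomes, cutoff: float) -> dict[str, float]:
    """PPV/NPV/sensitivity/specificity/accuracy at ``score >= cutoff``.

    Ratios with a zero denominator are reported as NaN, never as 0.
    """
    pred = scored.s >= cutoff
    tp = int(np.sum(pred & (scored.y == 1)))
    fp = int(np.sum(pred & (scored.y == 0)))
    fn = int(np.sum(~pred & (scored.y == 1)))
    tn = int(np.sum(~pred & (scored.y == 0)))

    def ratio(a, b):
        return a / b if b else float("nan")

    return {
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": (tp + tn) / scored.y.size,
    }


def f1_from(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of precision and recall; 0 by convention when both are 0."""
    if ppv == 0.0 and sensitivity == 0.0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def ppv_gain_per_100(ppv_new: float, ppv_old: float) -> float:
    """Patients per 100 on a referral list replaced by truly at-risk ones."""
    return (ppv_new - ppv_old) * 100.0


def brier(scored: ScoredOutcomes) -> float:
    """Mean squared error of risk scores against outcomes."""
    return float(np.mean((scored.s - scored.y) ** 2))


def stratified_folds(y: np.ndarray, k_folds: int, seed: int):
    """Stratified fold assignment, shuffled by ``seed``.

    The same fold object is reused for every pipeline in one optimizer run so
    that utilities are comparable across configurations.
    """
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if min(n_pos, n_neg) < k_folds:
        raise ValueError(
            f"stratified {k_folds}-fold CV needs at least {k_folds} samples of "
            f"each class (got {n_pos} positives, {n_neg} negatives)"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def cv_utility(config, dataset, k_folds: int = 10, seed: int = 0,
               folds=None) -> UtilityValue:
    """Clinical utility of a pipeline configuration by stratified k-fold CV.

    Parameters
    ----------
    config : PipelineConfig
        Pipeline to evaluate (fit on each training split via
        :func:`riskpipe.pipeline_space.assemble_and_fit`).
    dataset : LabeledDataset
    k_folds : int
        Number of stratified folds (ignored when ``folds`` is given).
    seed : int
        Controls fold shuffling and every model fit.
    folds : optional
        Pre-computed fold index pairs, reused across pipelines.
    """
    from .pipeline_space import assemble_and_fit  # local import, no cycle at load

    if folds is None:
        folds = stratified_folds(dataset.y, k_folds, seed)
    per_fold, per_aucpr, per_ap = [], [], []
    for i, (tr, te) in enumerate(folds):
        fitted = assemble_and_fit(config, dataset.subset(tr), seed=seed + i)
        scored = ScoredOutcomes(dataset.y[te], fitted.predict(dataset.X.iloc[te]))
        per_aucpr.append(auc_pr(scored))
        per_ap.append(average_precision(scored))
        per_fold.append(0.5 * (per_aucpr[-1] + per_ap[-1]))
    return UtilityValue(
        utility=float(np.mean(per_fold)),
        auc_pr=float(np.mean(per_aucpr)),
        average_precision=float(np.mean(per_ap)),
        per_fold=tuple(per_fold),
        n_folds=len(folds),
        sd=float(np.std(per_fold, ddof=1)) if len(per_fold) > 1 else float("nan"),
    )


def metrics_report(scored: ScoredOutcomes) -> dict[str, float]:
    """All headline metrics for one scored set (Table-3-style row)."""
    j, cut = youden_j(scored)
    at_j = confusion_at_cutoff(scored, cut)
    return {
        "auc_roc": auc_roc(scored),
        "youden_j": j,
        "youden_cutoff": cut,
        "auc_pr": auc_pr(scored),
        "average_precision": average_precision(scored),
        "f1_at_youden": f1_from(at_j["ppv"], at_j["sensitivity"]),
        "brier": brier(scored),
        "clinical_utility": clinical_utility(scored),
    }


def cutoff_for_sensitivity(scored: ScoredOutcomes, target: float) -> float:
    """Smallest cutoff achieving at-least-target sensitivity."""
    thr, tp, _ = _threshold_counts(scored)
    sens = tp / scored.n_pos
    ok = np.where(sens >= target)[0]
    if ok.size == 0:
        return float(thr[-1])
    # thresholds descend; the first index reaching target has the largest
    # cutoff with sens>=target, but equal sensitivity may extend to higher
    # cutoffs only; among cutoffs attaining >= target pick the largest
    # threshold index (lowest cutoff) that still *first* reaches the target:
    k = int(ok[0])
    return float(thr[k])


def ci_normal(values, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the mean of per-fold values."""
    from scipy.stats import norm

    v = np.asarray(values, dtype=float)
    m = v.mean()
    if v.size < 2:
        return (m, m)
    se = v.std(ddof=1) / math.sqrt(v.size)
    z = norm.ppf(0.5 + level / 2)
    return (m - z * se, m + z * se)
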