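"""ROC analysis and Youden-optimal threshold discovery.

Built from first principles so the enumeration of thresholds is explicit
and auditable: the decision rule is "predict responder when score ≥
threshold", thresholds are a +∞ sentinel followed by the unique observed
scores in descending order, and tied scores collapse to a single ROC
point. AUC is the trapezoidal area under the (FPR, TPR) polyline, which
under this enumeration equals the Mann-Whitney pairwise concordance
probability with half credit for ties.

Orientation matters and is deliberately NOT auto-detected: higher score
must mean "more likely responder". For scores where lower values predict
response (e.g. post-treatment uptake), callers negate the score; an AUC
below 0.5 faithfully reports an anti-predictive orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from petpd.errors import ValidationError


@dataclass(frozen=True)
class ScoredCohort:
    """Continuous scores (TE % by default) with binary responder labels."""

    animal_ids: tuple[str, ...]
    scores: tuple[float, ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if len(self.scores) != n or len(self.labels) != n:
            raise ValidationError("animal_ids, scores, labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")
        if set(self.labels) - {0, 1}:
            raise ValidationError("labels must be 0 or 1")

    @classmethod
    def from_arrays(
        cls,
        scores: Sequence[float],
        labels: Sequence[int],
        animal_ids: Sequence[str] | None = None,
    ) -> "ScoredCohort":
        if animal_ids is None:
            animal_ids = [f"a{i:03d}" for i in range(len(list(scores)))]
        return cls(tuple(animal_ids), tuple(float(s) for s in scores), tuple(int(x) for x in labels))


@dataclass(frozen=True)
class ROCResult:
    """One ROC curve: thresholds (descending, +∞ first), TPR/FPR per
    threshold, trapezoidal AUC, and — once Youden analysis has run — the
    optimal threshold and its J = TPR − FPR."""

    thresholds: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    auc: float
    youden_threshold: float | None = None
    youden_j: float | None = None


def roc_curve(cohort: ScoredCohort) -> ROCResult:
    """Enumerate the ROC curve of score vs label.

    Raises :class:`ValidationError` naming the missing class if the
    labels are single-class.
    """
    scores = np.asarray(cohort.scores, dtype=float)
    labels = np.asarray(cohort.labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0:
        raise ValidationError("no positive (responder) labels in cohort")
    if n_neg == 0:
        raise ValidationError("no negative (nonresponder) labels in cohort")

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    # predicted positive when score >= threshold
    tpr = np.array([(labels[scores >= t] == 1).sum() / n_pos for t in thresholds])
    fpr = np.array([(labels[scores >= t] == 0).sum() / n_neg for t in thresholds])
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=tuple(thresholds), tpr=tuple(tpr), fpr=tuple(fpr), auc=area
    )


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the (FPR, TPR) curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def youden_optimal(roc: ROCResult) -> tuple[float, float]:
    """Threshold maximizing Youden's J = TPR − FPR, with its J.

    Among thresholds attaining the maximum, the smallest is returned:
    it admits the most animals into the predicted-responder stratum,
    favoring sensitivity, and makes the choice deterministic. The +∞
    sentinel guarantees J ≥ 0.
    """
    j = np.asarray(roc.tpr) - np.asarray(roc.fpr)
    best_j = float(j.max())
    # thresholds are descending, so the last maximizer is the smallest
    best_idx = int(np.flatnonzero(j == best_j)[-1])
    return float(roc.thresholds[best_idx]), best_j


def analyze(cohort: ScoredCohort) -> ROCResult:
    """ROC curve with the Youden fields filled in."""
    roc = roc_curve(cohort)
    thr, j = youden_optimal(roc)
    return ROCResult(
        thresholds=roc.thresholds,
        tpr=roc.tpr,
        fpr=roc.fpr,
        auc=roc.auc,
        youden_threshold=thr,
        youden_j=j,
    )


def stratified_response_rate(
    cohort: ScoredCohort, threshold: float
) -> dict[str, float | None | tuple[int, int]]:
    """Responder rates below vs at-or-above a score threshold.

    Returns a dict with ``rate_below`` / ``rate_at_or_above`` as
    percentages (``None`` when the stratum is empty — undefined, not 0)
    and ``counts_below`` / ``counts_at_or_above`` as (responders, total).
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    scores = np.asarray(cohort.scores, dtype=float)
    labels = np.asarray(cohort.labels, dtype=int)

    def stratum(mask: np.ndarray) -> tuple[float | None, tuple[int, int]]:
        total = int(mask.sum())
        if total == 0:
            return None, (0, 0)
        responders = int(labels[mask].sum())
        return 100.0 * responders / total, (responders, total)

    rate_lo, counts_lo = stratum(scores < threshold)
    rate_hi, counts_hi = stratum(scores >= threshold)
    return {
        "rate_below": rate_lo,
        "rate_at_or_above": rate_hi,
        "counts_below": counts_lo,
        "counts_at_or_above": counts_hi,
    }


def pairwise_concordance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force Mann-Whitney AUC: fraction of (positive, negative)
    pairs where the positive outscores the negative, ties half credit.

    O(n_pos × n_neg); the independent oracle the trapezoidal AUC must
    agree with exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes required")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
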