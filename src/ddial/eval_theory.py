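"""Retrieval evaluation and the closed-form imbalance theory.

Evaluation is precision at a fixed recall floor: a literature-screening
workflow fixes recall at 0.95 so that at most 5% of relevant abstracts are
missed, and reports the precision achievable under that constraint.

The theory covers two analytic results about active learning (AL) over a
hugely imbalanced pool of N+ positives and N- >> N+ negatives:

* Random-negative pseudo-labelling injects n_mis mislabeled positives into
  the training negatives.  Before any calibration the error is
  eps + n_mis/(N- + N+); each AL review round calibrates the mislabeled
  negatives the model flags as positive, multiplying the mislabel term by
  (N+ + n_mis*N+/(N- + N+)) / (N- + N+) — a geometric decay (about 1/5 per
  step at n_mis = N-/1000, N+ = N-/4).

* Positive sampling (reviewing the top-alpha fraction of positively
  predicted documents) selects a given positive sample
  (alpha/eps) x (N- + N+)/N+ times more often than uncertainty sampling
  does — 501-fold at alpha = eps = 0.20, N+ = 5e4, N- = 2.5e7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ImbalanceScenario:
    """Population counts and rates for the closed-form theory.

    Parameters
    ----------
    N_pos, N_neg
        Population positive / negative counts (N+, N-).
    n_mis
        Mislabeled positives hidden among the pseudo-labelled negatives.
    eps
        Base misclassification error of the classifier (0..1).
    alpha
        Fraction of top positively-predicted documents reviewed under
        positive sampling (0..1].
    """

    N_pos: float
    N_neg: float
    n_mis: float = 0.0
    eps: float = 0.2
    alpha: float = 0.2

    def __post_init__(self) -> None:
        if self.N_pos < 0 or self.N_neg < 0 or self.n_mis < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.eps <= 1:
            raise ValueError("eps must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.N_neg and self.n_mis > self.N_neg / 10:
            warnings.warn(
                "n_mis exceeds N_neg/10; the small-mislabel approximation "
                "behind the decay formula is strained", stacklevel=2,
            )


@dataclass
class RetrievalMetrics:
    precision: float
    recall: float
    f1: float
    threshold: float


def _population(s: ImbalanceScenario) -> float:
    total = s.N_neg + s.N_pos
    if total <= 0:
        raise ValueError("empty population")
    return total


def error_before_al(s: ImbalanceScenario) -> float:
    """eps + n_mis/(N- + N+): base error plus the mislabel contamination."""
    return s.eps + s.n_mis / _population(s)


def mislabel_reduction_factor(s: ImbalanceScenario) -> float:
    """Per-step multiplicative factor applied to the mislabel term.

    One review round flags and corrects the mislabeled negatives the model
    predicts positive, leaving the term scaled by
    (N+ + n_mis*N+/(N- + N+)) / (N- + N+).
    """
    total = _population(s)
    return (s.N_pos + s.n_mis * s.N_pos / total) / total


def error_after_al(s: ImbalanceScenario, m_steps: int = 1) -> float:
    """Error after ``m_steps`` calibration rounds; decay is exactly geometric."""
    if m_steps < 0:
        raise ValueError("m_steps must be >= 0")
    term = s.n_mis / _population(s)
    return s.eps + term * mislabel_reduction_factor(s) ** m_steps


def positive_sampling_advantage(s: ImbalanceScenario) -> float:
    """(alpha/eps) x (N- + N+)/N+ — the fold-increase in the chance that a
    given positive document is selected for review under positive sampling
    versus uncertainty sampling."""
    if s.eps == 0:
        raise ValueError("advantage undefined at eps = 0")
    if s.N_pos == 0:
        raise ValueError("advantage undefined with no positives")
    return (s.alpha / s.eps) * _population(s) / s.N_pos


def estimate_pool_positives(total: int, reviewed: int, found_positive: int) -> int:
    """Scale a spot-check positive rate up to the whole pool.

    E.g. 25 positives in a 1,000-document review of a 142,520-document pool
    estimates round(142520 * 25/1000) = 3,563 relevant abstracts.
    """
    if reviewed < 1:
        raise ValueError("reviewed must be >= 1")
    if found_positive > reviewed:
        raise ValueError("found_positive cannot exceed reviewed")
    return round(total * found_positive / reviewed)


def precision_at_recall(
    scores: dict[str, float],
    truth: dict[str, str],
    target_recall: float = 0.95,
) -> RetrievalMetrics:
    """Best precision over all thresholds whose recall is >= the floor.

    Sweeps every distinct score as a >=-threshold; among thresholds
    achieving recall >= ``target_recall`` returns the one maximising
    precision (the all-inclusive threshold always reaches recall 1, so a
    feasible threshold exists whenever there is a true positive).
    """
    doc_ids = sorted(scores)
    y = np.array([1 if truth[d] == "positive" else 0 for d in doc_ids])
    p = np.array([scores[d] for d in doc_ids], dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no true positives in the truth map")

    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted)
    k = np.arange(1, len(y) + 1)
    # threshold candidates: last index of each distinct score value
    last_of_value = np.nonzero(np.r_[p_sorted[1:] != p_sorted[:-1], True])[0]
    prec = tp[last_of_value] / k[last_of_value]
    rec = tp[last_of_value] / n_pos
    feasible = rec >= target_recall
    assert feasible.any(), "threshold sweep must reach recall 1"
    best = np.argmax(np.where(feasible, prec, -1.0))
    P, R = float(prec[best]), float(rec[best])
    f1 = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return RetrievalMetrics(
        precision=P, recall=R, f1=f1, threshold=float(p_sorted[last_of_value[best]])
    )
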