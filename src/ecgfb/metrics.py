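"""Per-class evaluation: precision/recall/F1, ROC/AUC, paired Wilcoxon.

Precision_i = TP_i / (TP_i + FP_i), Recall_i = TP_i / (TP_i + FN_i) and
F1_i is their harmonic mean; 0/0 cases (no predicted positives, or no true
positives) are defined as 0 and flagged so macro averages over rare classes
stay finite.  The ROC curve sweeps the decision threshold over the unique
scores; AUC is the trapezoidal area, which with half-credit for ties equals
the probability that a random positive outranks a random negative.

The paired Wilcoxon signed-rank test compares two matched sets of F1
scores (e.g. the two preprocessing arms): exact tie-aware null
distribution up to n = 25 paired differences, normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    degenerate: bool  # a 0/0 convention was applied somewhere


@dataclass
class EvalReport:
    """Evaluation summary across classes."""

    per_class: dict[str, ClassMetrics]
    roc: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc: dict[str, float]
    macro_f1: float
    macro_auc: float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"precision": m.precision, "recall": m.recall,
                    "f1": m.f1, "degenerate": m.degenerate}
                for c, m in self.per_class.items()
            },
            "auc": dict(self.auc),
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
        }


def confusion(calls, truth) -> ConfusionCounts:
    """Confusion counts from 0/1 predictions and 0/1 truth."""
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} calls vs {truth.shape} truth")
    if calls.size < 1:
        raise ValueError("need at least one prediction")
    return ConfusionCounts(
        tp=int(np.sum((calls == 1) & (truth == 1))),
        fp=int(np.sum((calls == 1) & (truth == 0))),
        fn=int(np.sum((calls == 0) & (truth == 1))),
        tn=int(np.sum((calls == 0) & (truth == 0))),
    )


def prf1(c: ConfusionCounts) -> ClassMetrics:
    """Precision, recall and F1 with the 0/0 -> 0 (flagged) convention."""
    degenerate = False
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0.0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassMetrics(precision, recall, f1, degenerate)


def roc_auc(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC for one class.

    Returns (fpr, tpr, auc).  Ties in the scores earn half credit, so the
    AUC equals the pairwise probability-of-correct-ranking statistic.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    fpr, tpr, _ = roc_curve(truth, scores)
    return fpr, tpr, float(roc_auc_score(truth, scores))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p-value of the signed-rank statistic.

    Enumerates the null distribution of W+ over all 2^n equiprobable sign
    assignments by dynamic programming on doubled (hence integer) midranks,
    which handles ties exactly.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    # counts[s] = number of sign assignments with doubled W+ == s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    n_assign = counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[:w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(f1_a, f1_b, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (the usual convention); absolute
    differences are midranked.  Up to ``exact_max_n`` retained pairs the
    exact null distribution is enumerated; beyond that a tie-corrected
    normal approximation is used.
    """
    a = np.asarray(f1_a, dtype=float)
    b = np.asarray(f1_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    from scipy.stats import norm

    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def evaluate(truth_by_class: dict[str, np.ndarray],
             calls_by_class: dict[str, np.ndarray],
             scores_by_class: dict[str, np.ndarray] | None = None) -> EvalReport:
    """Assemble the per-class and macro evaluation report.

    Macro averages are unweighted means over classes; AUC for a class is
    omitted (and excluded from the macro) when its truth is single-class.
    """
    per_class: dict[str, ClassMetrics] = {}
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    auc: dict[str, float] = {}
    for cls, truth in truth_by_class.items():
        per_class[cls] = prf1(confusion(calls_by_class[cls], truth))
        if scores_by_class is not None and len(np.unique(truth)) == 2:
            fpr, tpr, a = roc_auc(scores_by_class[cls], truth)
            roc[cls] = (fpr, tpr)
            auc[cls] = a
    macro_f1 = float(np.mean([m.f1 for m in per_class.values()]))
    macro_auc = float(np.mean(list(auc.values()))) if auc else float("nan")
    return EvalReport(per_class=per_class, roc=roc, auc=auc,
                      macro_f1=macro_f1, macro_auc=macro_auc)
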