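"""ROC evaluation of the fitted model on the held-out standard test set.

The classifier score of a pair is its composite likelihood ratio. Sweeping a
threshold over the distinct scores (tied scores enter at a single step, so
ties contribute diagonal segments) yields the ROC curve of true-positive
rate against false-positive rate; the trapezoidal area under it equals the
Mann–Whitney concordance probability with ties counted 1/2 — the probability
that a random positive outscores a random negative. Sensitivity and
specificity at an operating threshold follow the usual definitions:

    sensitivity = TP / positives        specificity = 1 − FP / negatives
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import LikelihoodModel, score_table
from .pairs import ProteinPair


class LeakageError(RuntimeError):
    """Test positives were found in the training gold-positive set."""


@dataclass
class RocCurve:
    """ROC sweep: one row per distinct score threshold, descending."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positives: int
    negatives: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tpr": self.tpr,
                "fpr": self.fpr,
            }
        )


def sensitivity_specificity(
    tp: int, fp: int, positives: int, negatives: int
) -> tuple[float, float]:
    """(TP/positives, 1 − FP/negatives) with bounds checked."""
    if positives < 1 or negatives < 1:
        raise ValueError("positives and negatives must each be >= 1")
    if not 0 <= tp <= positives:
        raise ValueError(f"tp={tp} outside [0, {positives}]")
    if not 0 <= fp <= negatives:
        raise ValueError(f"fp={fp} outside [0, {negatives}]")
    return tp / positives, 1.0 - fp / negatives


def roc_curve(scores: list[tuple[float, bool]]) -> RocCurve:
    """ROC curve and trapezoidal AUC from (score, is_positive) items.

    Thresholds are the distinct scores in descending order; at each, a pair
    is called positive iff its score is >= the threshold. The curve is
    anchored at (0, 0); trapezoidal integration makes the area equal to the
    ties-as-1/2 Mann–Whitney concordance probability.
    """
    y = np.array([bool(lab) for _, lab in scores])
    s = np.array([float(v) for v, _ in scores])
    positives = int(y.sum())
    negatives = int(len(y) - positives)
    if positives == 0 or negatives == 0:
        raise ValueError("need at least one positive and one negative")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    # last index of each run of tied scores
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    last = np.concatenate([distinct, [len(s_sorted) - 1]])
    thresholds = s_sorted[last]
    tp = cum_tp[last]
    fp = cum_fp[last]
    tpr = tp / positives
    fpr = fp / negatives
    auc = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))
    return RocCurve(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        positives=positives,
        negatives=negatives,
    )


def evaluate_on_sts(
    sts: list[tuple[ProteinPair, bool]],
    evidence: pd.DataFrame,
    model: LikelihoodModel,
    lr_cutoff: float | None = None,
) -> tuple[RocCurve, dict[str, float]]:
    """Score the standard test set and summarize classifier performance.

    Scores are composite LRs from ``model``. If the model records its
    training GSP, any test positive found there aborts with
    :class:`LeakageError` naming the offending pairs. The summary reports the
    AUC plus sensitivity and specificity at ``lr_cutoff`` (when given).
    """
    if model.training_gsp is not None:
        leaked = sorted(p for p, lab in sts if lab and p in model.training_gsp)
        if leaked:
            shown = ", ".join(f"{a}-{b}" for a, b in leaked[:5])
            raise LeakageError(
                f"{len(leaked)} STS positive(s) found in training GSP: {shown}"
            )
    pairs = [p for p, _ in sts]
    missing = [p for p in pairs if p not in evidence.index]
    if missing:
        raise ValueError(f"{len(missing)} STS pair(s) missing from evidence table")
    lrs = score_table(evidence.loc[pairs], model)
    scored = [(float(lrs[p]), lab) for p, lab in sts]
    curve = roc_curve(scored)
    summary: dict[str, float] = {
        "auc": curve.auc,
        "positives": curve.positives,
        "negatives": curve.negatives,
    }
    if lr_cutoff is not None:
        tp = sum(1 for v, lab in scored if lab and v >= lr_cutoff)
        fp = sum(1 for v, lab in scored if not lab and v >= lr_cutoff)
        sens, spec = sensitivity_specificity(
            tp, fp, curve.positives, curve.negatives
        )
        summary.update(
            lr_cutoff=lr_cutoff, tp=tp, fp=fp, sensitivity=sens, specificity=spec
        )
    return curve, summary
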