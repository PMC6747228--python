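"""Binary-classification evaluation: ACC/SN/SP/MCC, ROC AUC, and the
jackknife (leave-one-out) and independent-test protocols.

The metric formulas are expressed in terms of class totals and error counts
(N⁺ positives, N⁻ negatives, N⁺⁻ false positives, N⁻⁺ false negatives):

    ACC = 1 − (N⁻⁺ + N⁺⁻) / (N⁺ + N⁻)
    SN  = 1 − N⁻⁺ / N⁺
    SP  = 1 − N⁺⁻ / N⁻
    MCC = (1 − (N⁻⁺/N⁺ + N⁺⁻/N⁻))
          / sqrt( (1 + (N⁺⁻ − N⁻⁺)/N⁺) · (1 + (N⁻⁺ − N⁺⁻)/N⁻) )

This MCC parameterization is algebraically identical to the usual
TP/TN/FP/FN form (the test suite checks that exhaustively).  In the
jackknife protocol every stage that sees data — bandwidth heuristics, MKL
weights, memberships, the ridge fit — is recomputed on each leave-one-out
training set, so no information about the held-out sample leaks in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.stats import rankdata

from .exceptions import ValidationError
from .features import FeatureMatrix
from .fkrr import FKRRModel, PipelineParams, train_full_pipeline


@dataclass
class ConfusionCounts:
    """Class totals and error counts of a binary prediction."""

    n_plus: int       # total positives (label +1)
    n_minus: int      # total negatives (label −1)
    n_plus_minus: int  # false positives: negatives predicted +1
    n_minus_plus: int  # false negatives: positives predicted −1

    def __post_init__(self) -> None:
        if not (0 <= self.n_minus_plus <= self.n_plus):
            raise ValidationError(
                f"false negatives {self.n_minus_plus} outside [0, {self.n_plus}]"
            )
        if not (0 <= self.n_plus_minus <= self.n_minus):
            raise ValidationError(
                f"false positives {self.n_plus_minus} outside [0, {self.n_minus}]"
            )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValidationError("prediction/label length mismatch")
        return cls(
            n_plus=int(np.sum(y_true == 1)),
            n_minus=int(np.sum(y_true == -1)),
            n_plus_minus=int(np.sum((y_true == -1) & (y_pred == 1))),
            n_minus_plus=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass
class MetricSet:
    """ACC/SN/SP/MCC; a metric whose denominator vanishes is None, with the
    offending zero named in ``undefined``."""

    acc: Optional[float]
    sn: Optional[float]
    sp: Optional[float]
    mcc: Optional[float]
    undefined: dict = field(default_factory=dict)


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    np_, nm = c.n_plus, c.n_minus
    fp, fn = c.n_plus_minus, c.n_minus_plus
    undefined: dict = {}

    acc = sn = sp = mcc = None
    if np_ + nm > 0:
        acc = 1.0 - (fn + fp) / (np_ + nm)
    else:
        undefined["acc"] = "no samples (N+ + N- = 0)"
    if np_ > 0:
        sn = 1.0 - fn / np_
    else:
        undefined["sn"] = "no positive samples (N+ = 0)"
    if nm > 0:
        sp = 1.0 - fp / nm
    else:
        undefined["sp"] = "no negative samples (N- = 0)"

    if np_ > 0 and nm > 0:
        denom_sq = (1.0 + (fp - fn) / np_) * (1.0 + (fn - fp) / nm)
        if denom_sq > 0:
            mcc = (1.0 - (fn / np_ + fp / nm)) / math.sqrt(denom_sq)
        else:
            undefined["mcc"] = (
                "zero MCC denominator (a predicted class is empty)"
            )
    else:
        undefined["mcc"] = "a true class is empty"
    return MetricSet(acc=acc, sn=sn, sp=sp, mcc=mcc, undefined=undefined)


def auc(decision_values, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic; tied
    decision values contribute 1/2."""
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(d)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Aggregated result of an evaluation protocol."""

    protocol: str
    counts: ConfusionCounts
    metrics: MetricSet
    auc: float
    ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    decisions: np.ndarray

    def as_dict(self) -> dict:
        m = self.metrics
        return {
            "protocol": self.protocol,
            "n_plus": self.counts.n_plus,
            "n_minus": self.counts.n_minus,
            "false_positives": self.counts.n_plus_minus,
            "false_negatives": self.counts.n_minus_plus,
            "acc": m.acc,
            "sn": m.sn,
            "sp": m.sp,
            "mcc": m.mcc,
            "auc": self.auc,
            "undefined": m.undefined,
        }

    def format_table(self) -> str:
        m = self.metrics

        def pct(v):
            return "undef" if v is None else f"{100 * v:6.2f}%"

        mcc = "undef" if m.mcc is None else f"{m.mcc:7.4f}"
        return (
            f"protocol: {self.protocol}\n"
            f"  ACC {pct(m.acc)}   SN {pct(m.sn)}   Spec {pct(m.sp)}   "
            f"MCC {mcc}   AUC {self.auc:7.4f}"
        )


def jackknife(
    views: Mapping[str, FeatureMatrix],
    y,
    params: Optional[PipelineParams] = None,
) -> EvaluationReport:
    """Leave-one-out evaluation: each sample is predicted by a pipeline
    retrained from scratch (bandwidths, MKL weights, memberships, fit) on
    the other N−1 samples."""
    if not views:
        raise ValidationError("no feature views supplied")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValidationError(f"jackknife needs N >= 3, got {n}")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValidationError("jackknife needs both classes present")

    first = next(iter(views.values()))
    ids = first.ids
    decisions = np.empty(n)
    preds = np.empty(n, dtype=int)
    for t in range(n):
        keep = np.concatenate([np.arange(t), np.arange(t + 1, n)])
        y_train = y[keep]
        if not (np.any(y_train == 1) and np.any(y_train == -1)):
            raise ValidationError(
                f"fold {t}: training set contains a single class"
            )
        train_views = {name: fm.subset(keep) for name, fm in views.items()}
        test_views = {name: fm.subset([t]) for name, fm in views.items()}
        model = train_full_pipeline(train_views, y_train, params)
        labels, dec = model.predict_views(test_views)
        preds[t] = labels[0]
        decisions[t] = dec[0]

    counts = ConfusionCounts.from_predictions(y, preds)
    return EvaluationReport(
        protocol="jackknife",
        counts=counts,
        metrics=metrics_from_counts(counts),
        auc=auc(decisions, y),
        ids=ids,
        y_true=y.astype(int),
        y_pred=preds,
        decisions=decisions,
    )


def independent_test(
    model: FKRRModel,
    test_views: Mapping[str, FeatureMatrix],
    y_test,
) -> EvaluationReport:
    """Evaluate a trained model on a held-out dataset."""
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size == 0:
        raise ValidationError("empty test set")
    first = next(iter(test_views.values()))
    if y_test.shape[0] != first.n:
        raise ValidationError("test label count does not match feature rows")
    preds, decisions = model.predict_views(test_views)
    counts = ConfusionCounts.from_predictions(y_test, preds)
    return EvaluationReport(
        protocol="independent",
        counts=counts,
        metrics=metrics_from_counts(counts),
        auc=auc(decisions, y_test),
        ids=first.ids,
        y_true=y_test.astype(int),
        y_pred=preds,
        decisions=decisions,
    )
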