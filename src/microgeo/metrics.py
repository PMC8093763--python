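"""Multiclass performance measures used for rank aggregation and reporting.

Three measures drive classifier selection — Cohen's kappa, the multiclass
geometric mean of recalls (G-mean), and the multiclass AUC of Hand & Till
(MAUC) — plus accuracy and per-class precision/recall for reporting.  All
are chance-aware alternatives to plain accuracy, which is insensitive to
rare classes in imbalanced city data.

Out-of-bag evaluation sets can lack classes entirely; every measure here is
computed over the classes present in the truth, with a logged note, so the
measures stay well-defined on any OOB draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts of truth class i (row) predicted as class j (column)."""

    classes: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix must be square over the class list")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        m = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(list(classes), m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class ScoreMatrix:
    """Per-sample class-membership scores aligned to a class list.

    Scores need not be probabilities: any per-class score that orders
    samples (e.g. SVM decision values) is valid for MAUC, which is invariant
    to strictly monotone transforms of each class's score column.
    """

    classes: list
    scores: np.ndarray  # (n_samples, n_classes)
    y_true: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=object)
        if self.scores.shape != (len(self.y_true), len(self.classes)):
            raise ValueError("scores shape must be (n_samples, n_classes)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class MetricReport:
    """One classifier's measures on one evaluation set."""

    kappa: float
    gmean: float
    mauc: float
    accuracy: float
    per_class_precision: dict = field(default_factory=dict)
    per_class_recall: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "gmean": self.gmean,
            "mauc": self.mauc,
            "accuracy": self.accuracy,
            "per_class_precision": dict(self.per_class_precision),
            "per_class_recall": dict(self.per_class_recall),
        }


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (P0 - PE) / (1 - PE).

    P0 is the observed agreement (overall accuracy) and PE the agreement
    expected under independent marginals.  Raises
    :class:`UndefinedMetricError` when PE = 1 (single-class truth and
    prediction), rather than silently returning 0.
    """
    total = cm.total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    m = cm.matrix / total
    p0 = np.trace(m)
    pe = float(m.sum(axis=1) @ m.sum(axis=0))
    if pe >= 1.0 - 1e-15:
        raise UndefinedMetricError("kappa undefined: expected agreement is 1")
    return float((p0 - pe) / (1.0 - pe))


def gmean(cm: ConfusionMatrix) -> float:
    """Geometric mean of per-class recalls over classes present in the truth.

    Any fully missed class annihilates the measure to 0.  Classes with no
    truth samples are excluded with a logged note.
    """
    row = cm.matrix.sum(axis=1)
    present = row > 0
    if not present.any():
        raise UndefinedMetricError("no truth samples")
    if not present.all():
        absent = [c for c, p in zip(cm.classes, present) if not p]
        logger.debug("gmean: excluding classes absent from truth: %s", absent)
    recalls = np.diag(cm.matrix)[present] / row[present]
    if np.any(recalls == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(recalls))))


def _pairwise_auc(scores_i: np.ndarray, mask_i: np.ndarray, mask_j: np.ndarray) -> float:
    """AUC(i, j): probability a class-i sample outranks a class-j sample on
    class-i scores, ties counted half (midranks)."""
    s = np.concatenate([scores_i[mask_i], scores_i[mask_j]])
    n_i, n_j = int(mask_i.sum()), int(mask_j.sum())
    ranks = rankdata(s, method="average")
    r_i = ranks[:n_i].sum()
    return float((r_i - n_i * (n_i + 1) / 2.0) / (n_i * n_j))


def mauc(sm: ScoreMatrix) -> float:
    """Hand-Till multiclass AUC: mean of AUC(i, j) over ordered class pairs.

    AUC(i, j) is the rank statistic of class-i scores restricted to samples
    of truth classes i and j.  Pairs with an empty side are skipped with the
    divisor adjusted.
    """
    present = [c for c in sm.classes if np.any(sm.y_true == c)]
    if len(present) < 2:
        raise UndefinedMetricError("MAUC needs at least two classes in the truth")
    if len(present) < len(sm.classes):
        logger.debug("mauc: classes absent from truth skipped: %s",
                     sorted(set(sm.classes) - set(present)))
    col = {c: k for k, c in enumerate(sm.classes)}
    total, n_pairs = 0.0, 0
    for i in present:
        mask_i = sm.y_true == i
        for j in present:
            if i == j:
                continue
            mask_j = sm.y_true == j
            total += _pairwise_auc(sm.scores[:, col[i]], mask_i, mask_j)
            n_pairs += 1
    return total / n_pairs


def precision_recall_by_class(cm: ConfusionMatrix) -> tuple[dict, dict]:
    """Per-class precision and recall maps.

    Precision of a class never predicted is ``None`` (undefined), not 0;
    recall of a class with no truth samples likewise.
    """
    col = cm.matrix.sum(axis=0)
    row = cm.matrix.sum(axis=1)
    diag = np.diag(cm.matrix)
    precision = {
        c: (float(diag[k] / col[k]) if col[k] > 0 else None)
        for k, c in enumerate(cm.classes)
    }
    recall = {
        c: (float(diag[k] / row[k]) if row[k] > 0 else None)
        for k, c in enumerate(cm.classes)
    }
    return precision, recall


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(cm.matrix) / cm.total)


def evaluate(y_true, y_pred, scores: ScoreMatrix | None = None, classes=None) -> MetricReport:
    """Bundle all measures for one prediction set into a MetricReport.

    ``mauc`` is NaN when no score matrix is supplied.
    """
    cm = ConfusionMatrix.from_labels(y_true, y_pred, classes=classes)
    prec, rec = precision_recall_by_class(cm)
    return MetricReport(
        kappa=cohens_kappa(cm),
        gmean=gmean(cm),
        mauc=mauc(scores) if scores is not None else float("nan"),
        accuracy=accuracy(cm),
        per_class_precision=prec,
        per_class_recall=rec,
    )
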