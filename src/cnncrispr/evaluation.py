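"""Classification/regression metrics and the two evaluation protocols.

Off-target test sets are extremely imbalanced (~250 negatives per positive),
so beyond Recall = TP / (TP + FN) the headline metrics are the areas under
the ROC and precision-recall curves — auPRC carries most of the signal,
since its constant-score floor is the prevalence while auROC's is 0.5.
Regression predictions are summarized by Pearson and Spearman correlation
against measured cleavage frequency.

Two protocols are provided: a withheld random test fraction (see
``data_io.split_train_test``) and leave-one-sgRNA-out cross-validation,
where all sites of one guide form the test fold — the stringent measure of
generalization to unseen guides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_at_threshold",
    "recall",
    "ranking_metrics",
    "correlation_metrics",
    "evaluate_scores",
    "leave_one_sgrna_out",
    "mean_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class EvaluationReport:
    """One evaluation's metric bundle; NaN marks an undefined metric."""

    recall: float
    auroc: float
    auprc: float
    pearson: float
    spearman: float
    n_pos: int
    n_neg: int
    sgrna_id: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        bad = labels[~np.isin(labels, (0, 1))][0]
        raise ValueError(f"labels must be binary, found {bad!r}")
    return labels.astype(np.int64)


def confusion_at_threshold(labels, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix with score >= threshold called positive."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {scores.shape} scores")
    called = scores >= threshold
    return ConfusionMatrix(
        TP=int(np.sum(called & (labels == 1))),
        FN=int(np.sum(~called & (labels == 1))),
        FP=int(np.sum(called & (labels == 0))),
        TN=int(np.sum(~called & (labels == 0))),
    )


def recall(matrix: ConfusionMatrix) -> float:
    """Recall = TP / (TP + FN); undefined without positives."""
    if matrix.TP + matrix.FN == 0:
        raise ValueError("recall undefined: no positive examples (TP + FN == 0)")
    return matrix.TP / (matrix.TP + matrix.FN)


def ranking_metrics(labels, scores) -> tuple[float, float]:
    """(auROC, auPRC) of scores against binary labels.

    auROC is the trapezoidal area with tied scores grouped into single
    threshold steps; auPRC is the area under the precision-recall step
    curve.  Requires both classes.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if labels.min() == labels.max():
        raise ValueError("ranking metrics undefined for single-class input")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def correlation_metrics(true_freq, predicted) -> tuple[float, float]:
    """(Pearson, Spearman) correlation between measured and predicted values.

    Spearman is Pearson on mid-ranks (average-rank tie handling).  Both are
    undefined when either vector has zero variance.
    """
    true_freq = np.asarray(true_freq, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if true_freq.shape != predicted.shape:
        raise ValueError("vectors must have the same length")
    if true_freq.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.var(true_freq) == 0 or np.var(predicted) == 0:
        raise ValueError("correlation undefined: zero variance in an input vector")
    pearson = float(stats.pearsonr(true_freq, predicted).statistic)
    spearman = float(stats.spearmanr(true_freq, predicted).statistic)
    return pearson, spearman


def evaluate_scores(
    labels,
    scores,
    frequencies=None,
    threshold: float = 0.5,
    sgrna_id: str | None = None,
) -> EvaluationReport:
    """Bundle every metric for one set of predictions.

    Ranking metrics are NaN on single-class input; correlations are NaN
    when undefined (zero variance) or when no frequencies are supplied.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    rec = auroc = auprc = pearson = spearman = math.nan
    if n_pos > 0:
        rec = recall(confusion_at_threshold(labels, scores, threshold))
    if n_pos > 0 and n_neg > 0:
        auroc, auprc = ranking_metrics(labels, scores)
    if frequencies is not None:
        try:
            pearson, spearman = correlation_metrics(frequencies, scores)
        except ValueError:
            pass
    return EvaluationReport(
        recall=rec, auroc=auroc, auprc=auprc, pearson=pearson, spearman=spearman,
        n_pos=n_pos, n_neg=n_neg, sgrna_id=sgrna_id,
    )


def leave_one_sgrna_out(
    data: Dataset,
    trainer: Callable,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[list[EvaluationReport], EvaluationReport]:
    """Leave-one-sgRNA-out cross-validation.

    One fold per distinct sgRNA id: the fold's test set is every pair of
    that guide, the training set everything else.  ``trainer`` has
    signature ``trainer(train_data, seed) -> scorer``, with
    ``scorer(test_data)`` returning one score per pair.  Folds whose test
    set is single-class keep a defined recall but get NaN ranking metrics;
    NaN metrics are excluded from the mean with a logged notice.
    """
    ids = data.unique_sgrna_ids()
    if len(ids) < 2:
        raise ValueError("leave-one-sgRNA-out needs at least 2 distinct sgRNA ids")
    reports: list[EvaluationReport] = []
    for fold, sgrna_id in enumerate(ids):
        test_idx = [i for i, p in enumerate(data) if p.sgrna_id == sgrna_id]
        train_idx = [i for i, p in enumerate(data) if p.sgrna_id != sgrna_id]
        test_set = data.subset(test_idx)
        train_set = data.subset(train_idx)
        scorer = trainer(train_set, seed=seed + fold)
        scores = np.asarray(scorer(test_set), dtype=np.float64)
        report = evaluate_scores(
            test_set.labels, scores, frequencies=test_set.frequencies,
            threshold=threshold, sgrna_id=sgrna_id,
        )
        if math.isnan(report.auroc):
            logger.warning(
                "fold %s (%s): single-class test set; ranking metrics undefined "
                "and excluded from the mean", fold, sgrna_id,
            )
        reports.append(report)
    return reports, mean_report(reports)


def mean_report(reports: list[EvaluationReport]) -> EvaluationReport:
    """Per-metric mean over folds, ignoring NaN (undefined) entries."""

    def nanmean(values: list[float]) -> float:
        finite = [v for v in values if not math.isnan(v)]
        return float(np.mean(finite)) if finite else math.nan

    return EvaluationReport(
        recall=nanmean([r.recall for r in reports]),
        auroc=nanmean([r.auroc for r in reports]),
        auprc=nanmean([r.auprc for r in reports]),
        pearson=nanmean([r.pearson for r in reports]),
        spearman=nanmean([r.spearman for r in reports]),
        n_pos=int(sum(r.n_pos for r in reports)),
        n_neg=int(sum(r.n_neg for r in reports)),
        sgrna_id=None,
    )
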