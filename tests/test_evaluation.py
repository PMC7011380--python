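"""Metrics and evaluation protocols."""

import itertools
import math

import numpy as np
import pytest

from cnncrispr.cfd import score_dataset
from cnncrispr.data_io import Dataset, SgRnaDnaPair
from cnncrispr.evaluation import (
    ConfusionMatrix,
    confusion_at_threshold,
    correlation_metrics,
    evaluate_scores,
    leave_one_sgrna_out,
    mean_report,
    ranking_metrics,
    recall,
)

SEQ = "ACGTACGTACGTACGTACGTAGG"


def auroc_concordant_pairs(labels, scores):
    """Independent oracle: concordant-pair fraction with tie correction."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_confusion_counts_match_hand_tally():
    labels = [1, 1, 1, 0, 0, 0, 0, 1, 0, 0]
    scores = [0.9, 0.4, 0.6, 0.1, 0.8, 0.3, 0.5, 0.5, 0.2, 0.7]
    m = confusion_at_threshold(labels, scores, 0.5)
    assert (m.TP, m.FN, m.FP, m.TN) == (3, 1, 3, 3)
    assert m.total == 10


def test_perfect_predictor_has_no_errors():
    labels = np.array([0, 1, 0, 1])
    m = confusion_at_threshold(labels, labels.astype(float), 0.5)
    assert m.FP == 0 and m.FN == 0


def test_all_zero_scores_miss_every_positive():
    labels = np.array([1, 1, 0, 1])
    m = confusion_at_threshold(labels, np.zeros(4), 0.5)
    assert m.TP == 0 and m.FN == 3


def test_non_binary_labels_rejected():
    with pytest.raises(ValueError, match="binary"):
        confusion_at_threshold([0, 2], [0.1, 0.2])


def test_recall_is_tp_over_tp_plus_fn():
    assert recall(ConfusionMatrix(TP=8, FN=2, FP=5, TN=5)) == pytest.approx(0.8)
    assert recall(ConfusionMatrix(TP=0, FN=4, FP=0, TN=0)) == 0.0
    with pytest.raises(ValueError, match="no positive"):
        recall(ConfusionMatrix(TP=0, FN=0, FP=1, TN=1))


def test_recall_cross_checks_against_sklearn():
    from sklearn.metrics import recall_score
    rng = np.random.default_rng(0)
    for _ in range(100):
        labels = rng.integers(0, 2, 30)
        if labels.sum() == 0:
            continue
        scores = rng.random(30)
        ours = recall(confusion_at_threshold(labels, scores, 0.5))
        theirs = recall_score(labels, (scores >= 0.5).astype(int))
        assert ours == pytest.approx(theirs)


def test_auroc_matches_concordant_pair_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(5, 31))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        auroc, _ = ranking_metrics(labels, scores)
        assert auroc == pytest.approx(auroc_concordant_pairs(labels, scores), abs=1e-12)


def test_perfect_separation_gives_auroc_one():
    labels = np.array([0, 0, 0, 1, 1])
    scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
    auroc, auprc = ranking_metrics(labels, scores)
    assert auroc == 1.0 and auprc == 1.0


def test_constant_scores_degenerate_to_chance():
    labels = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
    auroc, auprc = ranking_metrics(labels, np.full(10, 0.7))
    assert auroc == pytest.approx(0.5)
    assert auprc == pytest.approx(labels.mean())  # prevalence floor


def test_single_class_input_rejected():
    with pytest.raises(ValueError, match="single-class"):
        ranking_metrics(np.ones(5), np.random.default_rng(0).random(5))


def test_correlations_on_exact_and_reversed_predictions():
    rng = np.random.default_rng(2)
    truth = rng.random(20)
    p, s = correlation_metrics(truth, truth)
    assert p == pytest.approx(1.0) and s == pytest.approx(1.0)
    p, _ = correlation_metrics(truth, 1.0 - truth)
    assert p == pytest.approx(-1.0)


def test_spearman_handles_heavy_zero_inflation_with_midranks():
    """250:1-style zero-inflated truth vector against a manual
    rank-then-Pearson computation with average ranks for ties."""
    rng = np.random.default_rng(3)
    truth = np.zeros(251)
    truth[0] = 0.8
    pred = rng.random(251)

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rt, rp = midranks(truth), midranks(pred)
    manual = np.corrcoef(rt, rp)[0, 1]
    _, spearman = correlation_metrics(truth, pred)
    assert spearman == pytest.approx(manual, abs=1e-12)


def test_zero_variance_correlation_reported():
    with pytest.raises(ValueError, match="zero variance"):
        correlation_metrics(np.ones(5), np.random.default_rng(0).random(5))


def test_report_invariant_to_input_permutation():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 2, 40)
    labels[:3] = 1
    labels[3:6] = 0
    scores = rng.random(40)
    freqs = labels * rng.random(40)
    a = evaluate_scores(labels, scores, freqs)
    perm = rng.permutation(40)
    b = evaluate_scores(labels[perm], scores[perm], freqs[perm])
    for name in ("recall", "auroc", "auprc", "pearson", "spearman"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-12)


def cfd_trainer_factory(table):
    """Training-free scorer used to exercise the fold bookkeeping."""

    def trainer(train_data, seed=0):
        return lambda test_data: score_dataset(test_data, table)

    return trainer


def test_loso_folds_partition_by_sgrna(small_benchmark):
    data, table = small_benchmark
    reports, mean = leave_one_sgrna_out(data, cfd_trainer_factory(table), seed=0)
    assert len(reports) == len(data.unique_sgrna_ids())
    assert sum(r.n_pos + r.n_neg for r in reports) == len(data)
    fold_ids = [r.sgrna_id for r in reports]
    assert sorted(fold_ids) == sorted(data.unique_sgrna_ids())
    assert not math.isnan(mean.auroc)


def test_loso_excludes_single_class_folds_from_mean():
    # sgB has no positives: its ranking metrics are undefined
    g = SEQ
    pairs = [
        SgRnaDnaPair("sgA", g, g[:5] + "T" + g[6:], 1, 0.5),
        SgRnaDnaPair("sgA", g, g, 0, 0.0),
        SgRnaDnaPair("sgB", g, g, 0, 0.0),
        SgRnaDnaPair("sgB", g, g[:3] + "A" + g[4:] if g[3] != "A" else g, 0, 0.0),
    ]
    data = Dataset(pairs)

    def trainer(train_data, seed=0):
        return lambda test_data: np.linspace(0, 1, len(test_data))

    reports, mean = leave_one_sgrna_out(data, trainer, seed=0)
    by_id = {r.sgrna_id: r for r in reports}
    assert math.isnan(by_id["sgB"].auroc)
    assert not math.isnan(mean.auroc)  # mean over the defined folds only


def test_loso_requires_two_guides():
    data = Dataset([SgRnaDnaPair("sgA", SEQ, SEQ, 0, 0.0)] * 3)
    with pytest.raises(ValueError, match="at least 2"):
        leave_one_sgrna_out(data, lambda d, seed=0: (lambda t: np.zeros(len(t))))


def test_mean_report_averages_defined_metrics_only():
    from cnncrispr.evaluation import EvaluationReport
    r1 = EvaluationReport(0.5, 0.9, 0.4, math.nan, math.nan, 2, 10)
    r2 = EvaluationReport(1.0, math.nan, math.nan, math.nan, math.nan, 0, 10)
    mean = mean_report([r1, r2])
    assert mean.auroc == pytest.approx(0.9)
    assert mean.recall == pytest.approx(0.75)
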