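"""Imbalanced-data batch construction.

Off-target screens are dominated by negatives (~250 candidate loci per
validated site).  Training therefore partitions the M negatives of an epoch
into N = floor(M / m) disjoint subsets of size m (m is the batch-size
parameter, default 256) and pairs each subset with m positives drawn with
replacement — N oversampling draws per epoch.  Nearly all negatives are
visited each epoch (the M mod m leftovers roll into the next epoch's
shuffle), while every batch still carries positive signal.

Two batch compositions are supported: ``balanced`` (m negatives + m
positives, 2m total — the default) and ``compact`` (m/2 + m/2, total m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .data_io import Dataset

__all__ = ["BatchPlan", "plan_batches", "iterate_batches"]


@dataclass
class BatchPlan:
    """One epoch's batches as index lists into a dataset."""

    negative_batches: list[np.ndarray]
    positive_batches: list[np.ndarray]
    m: int
    seed: int
    composition: str = "balanced"

    @property
    def n_batches(self) -> int:
        return len(self.negative_batches)

    @property
    def batches(self) -> list[np.ndarray]:
        """Combined per-batch index lists (negatives then positives)."""
        return [
            np.concatenate([neg, pos])
            for neg, pos in zip(self.negative_batches, self.positive_batches)
        ]

    def to_json(self, path) -> None:
        payload = {
            "m": self.m,
            "seed": self.seed,
            "composition": self.composition,
            "negative_batches": [b.tolist() for b in self.negative_batches],
            "positive_batches": [b.tolist() for b in self.positive_batches],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path) -> "BatchPlan":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            negative_batches=[np.asarray(b, dtype=np.int64) for b in payload["negative_batches"]],
            positive_batches=[np.asarray(b, dtype=np.int64) for b in payload["positive_batches"]],
            m=payload["m"],
            seed=payload["seed"],
            composition=payload["composition"],
        )


def plan_batches(
    data: Dataset,
    m: int = 256,
    seed: int = 0,
    composition: str = "balanced",
    epoch: int = 0,
) -> BatchPlan:
    """Build one epoch's batch plan.

    Negatives are shuffled (seeded by ``(seed, epoch)``) and cut into
    N = floor(M / m) consecutive subsets; each subset gets an equal-sized
    draw of positives with replacement.  ``composition='balanced'`` uses m
    negatives + m positives per batch; ``'compact'`` uses m/2 + m/2.
    """
    if composition not in ("balanced", "compact"):
        raise ValueError(f"composition must be 'balanced' or 'compact', got {composition!r}")
    neg_per_batch = m if composition == "balanced" else m // 2
    if neg_per_batch < 1:
        raise ValueError(f"batch size m={m} too small for composition {composition!r}")
    negatives = data.negative_indices()
    positives = data.positive_indices()
    if positives.size == 0:
        raise ValueError("dataset has no positives; cannot oversample")
    if negatives.size < neg_per_batch:
        raise ValueError(
            f"need at least {neg_per_batch} negatives per batch, have {negatives.size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
    shuffled = rng.permutation(negatives)
    n_batches = negatives.size // neg_per_batch
    negative_batches = [
        shuffled[i * neg_per_batch:(i + 1) * neg_per_batch] for i in range(n_batches)
    ]
    positive_batches = [
        rng.choice(positives, size=neg_per_batch, replace=True) for _ in range(n_batches)
    ]
    return BatchPlan(negative_batches, positive_batches, m=m, seed=seed,
                     composition=composition)


def iterate_batches(
    plan: BatchPlan, data: Dataset
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Materialize batches in plan order.

    Yields ``(indices, labels, frequencies)`` per batch; each batch is
    internally shuffled (seeded) so positives and negatives interleave.
    """
    labels = data.labels
    frequencies = data.frequencies
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 7919]))
    for batch in plan.batches:
        if batch.max(initial=-1) >= len(data) or batch.min(initial=0) < 0:
            raise IndexError("batch plan index out of range for dataset")
        order = rng.permutation(batch.size)
        shuffled = batch[order]
        yield shuffled, labels[shuffled], frequencies[shuffled]
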