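"""GloVe embedding of the 16-token sgRNA-DNA vocabulary.

Each encoded pair is a length-23 "sentence" over the 16-word vocabulary of
aligned base combinations.  A symmetric-window co-occurrence matrix X is
accumulated over the corpus (no context crosses a sentence boundary), and
token vectors are fit by weighted least squares on log co-occurrence:

    J = sum_{x_ij > 0} f(x_ij) (v_i . v_j + b_i + b_j - log x_ij)^2

with the standard weighting f(x) = (x / x_max)^alpha for x < x_max, else 1.
Optimization is AdaGrad; with a 16-word vocabulary the full fit is
sub-second, so no sampling or sharding is needed.  The embedding handed to
the network is the sum of word and context vectors (the usual composition;
word-only is selectable).

Defaults: window 5 with inverse-distance weighting, x_max = 100,
alpha = 0.75, d = 100, 1000 AdaGrad iterations at initial rate 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .encoding import VOCAB_SIZE, TokenSequence

__all__ = [
    "CooccurrenceMatrix",
    "GloveParams",
    "build_cooccurrence",
    "cooccurrence_stats",
    "glove_cost",
    "glove_cost_grad",
    "fit_glove",
    "save_embedding",
    "load_embedding",
]


@dataclass
class CooccurrenceMatrix:
    """Weighted co-occurrence counts x_ij over the encoded corpus."""

    x: np.ndarray
    window: int
    distance_weighting: str = "inverse_distance"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (VOCAB_SIZE, VOCAB_SIZE):
            raise ValueError(f"co-occurrence matrix must be {VOCAB_SIZE}x{VOCAB_SIZE}")
        if (self.x < 0).any():
            raise ValueError("co-occurrence counts must be nonnegative")


@dataclass
class GloveParams:
    """Word/context vectors and biases plus the weighting-function knobs."""

    vectors: np.ndarray
    context_vectors: np.ndarray
    biases: np.ndarray
    context_biases: np.ndarray
    x_max: float = 100.0
    alpha: float = 0.75

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def embedding(self, combine: str = "sum") -> np.ndarray:
        """Final embedding matrix: word + context vectors, or word only."""
        if combine == "sum":
            e = self.vectors + self.context_vectors
        elif combine == "word":
            e = self.vectors.copy()
        else:
            raise ValueError(f"combine must be 'sum' or 'word', got {combine!r}")
        if not np.isfinite(e).all():
            raise ValueError("embedding contains non-finite entries")
        return e


def build_cooccurrence(
    corpus: Iterable[TokenSequence],
    window: int = 5,
    distance_weighting: str = "inverse_distance",
) -> CooccurrenceMatrix:
    """Accumulate x_ij within each length-23 sentence.

    For every ordered token position p and context position q with
    0 < |p - q| <= window, x[token_p, token_q] gains 1 (uniform) or
    1/|p - q| (inverse_distance).  Context never crosses sentences.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if distance_weighting not in ("uniform", "inverse_distance"):
        raise ValueError(f"unknown distance_weighting {distance_weighting!r}")
    x = np.zeros((VOCAB_SIZE, VOCAB_SIZE), dtype=np.float64)
    n_sentences = 0
    for sentence in corpus:
        n_sentences += 1
        idx = sentence.indices if isinstance(sentence, TokenSequence) else np.asarray(sentence)
        length = len(idx)
        for p in range(length):
            hi = min(length, p + window + 1)
            for q in range(p + 1, hi):
                w = 1.0 if distance_weighting == "uniform" else 1.0 / (q - p)
                x[idx[p], idx[q]] += w
                x[idx[q], idx[p]] += w
    if n_sentences == 0:
        raise ValueError("empty corpus")
    return CooccurrenceMatrix(x, window, distance_weighting)


def cooccurrence_stats(
    X: CooccurrenceMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row totals X_i, conditional probabilities P_ik and ratios P_ik/P_jk.

    Returns ``(row_totals, P, ratio)`` with ``P[i, k] = x[i, k] / X_i`` and
    ``ratio[i, j, k] = P[i, k] / P[j, k]`` (NaN where the denominator
    probability is zero).  Zero row totals are an error: every conditional
    probability of that row would be undefined.
    """
    row_totals = X.x.sum(axis=1)
    zero_rows = np.flatnonzero(row_totals == 0)
    if zero_rows.size:
        raise ValueError(
            f"token row(s) {zero_rows.tolist()} never occur: row total is zero, "
            "conditional probabilities are undefined"
        )
    P = X.x / row_totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = P[:, None, :] / P[None, :, :]
    return row_totals, P, ratio


def _weight(x: np.ndarray, x_max: float, alpha: float) -> np.ndarray:
    return np.where(x < x_max, (x / x_max) ** alpha, 1.0)


def glove_cost(params: GloveParams, X: CooccurrenceMatrix) -> float:
    """The weighted least-squares cost J, summed over nonzero cells only."""
    for arr in (params.vectors, params.context_vectors, params.biases, params.context_biases):
        if not np.isfinite(arr).all():
            raise ValueError("non-finite parameter values")
    mask = X.x > 0
    if not mask.any():
        raise ValueError("co-occurrence matrix has no positive entries")
    inner = params.vectors @ params.context_vectors.T
    resid = inner + params.biases[:, None] + params.context_biases[None, :]
    resid = np.where(mask, resid - np.log(np.where(mask, X.x, 1.0)), 0.0)
    f = np.where(mask, _weight(X.x, params.x_max, params.alpha), 0.0)
    return float((f * resid ** 2).sum())


def glove_cost_grad(
    params: GloveParams, X: CooccurrenceMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`glove_cost` in the order
    (vectors, context_vectors, biases, context_biases)."""
    mask = X.x > 0
    inner = params.vectors @ params.context_vectors.T
    resid = inner + params.biases[:, None] + params.context_biases[None, :]
    resid = np.where(mask, resid - np.log(np.where(mask, X.x, 1.0)), 0.0)
    f = np.where(mask, _weight(X.x, params.x_max, params.alpha), 0.0)
    common = 2.0 * f * resid  # dJ/d(inner_ij)
    grad_v = common @ params.context_vectors
    grad_c = common.T @ params.vectors
    grad_b = common.sum(axis=1)
    grad_cb = common.sum(axis=0)
    return grad_v, grad_c, grad_b, grad_cb


def fit_glove(
    X: CooccurrenceMatrix,
    d: int = 100,
    iterations: int = 1000,
    learning_rate: float = 0.05,
    seed: int = 0,
    x_max: float = 100.0,
    alpha: float = 0.75,
    combine: str = "sum",
) -> tuple[GloveParams, np.ndarray]:
    """Fit token vectors by full-batch AdaGrad on the GloVe cost.

    Returns the fitted parameters and the composed (16, d) embedding
    matrix.  Deterministic for a fixed seed; aborts if the cost diverges.
    """
    if d < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {d}")
    if not (X.x > 0).any():
        raise ValueError("co-occurrence matrix has no positive entries")
    rng = np.random.default_rng(seed)
    scale = 0.5 / np.sqrt(d)
    params = GloveParams(
        vectors=rng.uniform(-scale, scale, size=(VOCAB_SIZE, d)),
        context_vectors=rng.uniform(-scale, scale, size=(VOCAB_SIZE, d)),
        biases=rng.uniform(-scale, scale, size=VOCAB_SIZE),
        context_biases=rng.uniform(-scale, scale, size=VOCAB_SIZE),
        x_max=x_max,
        alpha=alpha,
    )
    arrays = [params.vectors, params.context_vectors, params.biases, params.context_biases]
    accum = [np.full_like(a, 1e-8) for a in arrays]
    cost_history = [glove_cost(params, X)]
    for it in range(iterations):
        grads = glove_cost_grad(params, X)
        for a, g, acc in zip(arrays, grads, accum):
            acc += g ** 2
            a -= learning_rate * g / np.sqrt(acc)
        cost = glove_cost(params, X)
        if not np.isfinite(cost):
            raise FloatingPointError(
                f"GloVe training diverged at iteration {it + 1}: cost is non-finite "
                f"(last finite cost {cost_history[-1]:.6g})"
            )
        cost_history.append(cost)
    params.cost_history = cost_history  # type: ignore[attr-defined]
    return params, params.embedding(combine)


def save_embedding(embedding: np.ndarray, path) -> None:
    """Serialize as text: one row per token (index then d floats)."""
    embedding = np.asarray(embedding)
    with open(path, "w") as handle:
        for token, row in enumerate(embedding):
            handle.write(str(token) + " " + " ".join(f"{v:.17g}" for v in row) + "\n")


def load_embedding(path) -> np.ndarray:
    """Inverse of :func:`save_embedding`."""
    rows: dict[int, list[float]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.split()
            if not fields:
                continue
            rows[int(fields[0])] = [float(v) for v in fields[1:]]
    if sorted(rows) != list(range(VOCAB_SIZE)):
        raise ValueError(f"embedding file must cover tokens 0..{VOCAB_SIZE - 1}")
    return np.array([rows[i] for i in range(VOCAB_SIZE)], dtype=np.float64)
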