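"""Pairwise sgRNA-DNA tokenization.

An aligned sgRNA-DNA pair of length 23 (20-nt protospacer + 3-nt PAM) is
encoded position by position: the ordered base combination (r, d) at each
site is one of 4 x 4 = 16 "words", so the pair becomes a length-23 vector of
integer token indices in [0, 15].  This index vector is the corpus unit on
which the GloVe embedding is trained and the input to the network.

The index convention is lexicographic: ``index = 4*order(r) + order(d)``
with A=0, C=1, G=2, T=3, so (A,A) -> 0, (A,C) -> 1, ..., (T,T) -> 15.
Any fixed bijection carries the same information; this one is the package's
canonical, serialization-stable choice, and the base order is configurable
for interoperability with artifacts that used a different assignment.

Positions are 0-based internally; user-facing messages are 1-based, with
positions 21-23 being the PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PAIR_LENGTH = 23
VOCAB_SIZE = 16
DEFAULT_BASE_ORDER = "ACGT"

__all__ = [
    "PAIR_LENGTH",
    "VOCAB_SIZE",
    "TokenSequence",
    "token_index",
    "encode_pair",
    "decode_tokens",
    "encode_dataset",
    "match_tokens",
    "mismatch_count",
]


def _base_rank(base: str, base_order: str) -> int:
    rank = base_order.find(base)
    if rank < 0:
        raise ValueError(f"non-canonical base {base!r}; expected one of {base_order}")
    return rank


@dataclass(frozen=True)
class TokenSequence:
    """Length-23 vector of token indices in [0, 15]."""

    indices: np.ndarray
    base_order: str = DEFAULT_BASE_ORDER

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.shape != (PAIR_LENGTH,):
            raise ValueError(
                f"token sequence must have length {PAIR_LENGTH}, got shape {idx.shape}"
            )
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= VOCAB_SIZE:
            bad = idx[(idx < 0) | (idx >= VOCAB_SIZE)][0]
            raise ValueError(f"token value {bad} outside [0, {VOCAB_SIZE - 1}]")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return PAIR_LENGTH


def token_index(rna_base: str, dna_base: str, base_order: str = DEFAULT_BASE_ORDER) -> int:
    """Token index of one aligned (sgRNA base, DNA base) combination.

    Bijective over the 16 ordered base pairs: ``4*rank(r) + rank(d)``.
    """
    if len(rna_base) != 1 or len(dna_base) != 1:
        raise ValueError("token_index takes single bases")
    return 4 * _base_rank(rna_base, base_order) + _base_rank(dna_base, base_order)


def encode_pair(
    sgrna_seq: str, dna_seq: str, base_order: str = DEFAULT_BASE_ORDER
) -> TokenSequence:
    """Encode an aligned 23-nt sgRNA-DNA pair as a length-23 token vector."""
    if len(sgrna_seq) != len(dna_seq):
        raise ValueError(
            f"length mismatch: sgRNA has {len(sgrna_seq)} nt, DNA has {len(dna_seq)} nt"
        )
    if len(sgrna_seq) != PAIR_LENGTH:
        raise ValueError(f"sequences must be {PAIR_LENGTH} nt, got {len(sgrna_seq)}")
    indices = np.empty(PAIR_LENGTH, dtype=np.int64)
    for i, (r, d) in enumerate(zip(sgrna_seq, dna_seq)):
        try:
            indices[i] = token_index(r, d, base_order)
        except ValueError as exc:
            raise ValueError(f"position {i + 1}: {exc}") from None
    return TokenSequence(indices, base_order)


def decode_tokens(tokens: TokenSequence) -> tuple[str, str]:
    """Exact inverse of :func:`encode_pair`: recover (sgRNA, DNA) sequences."""
    order = tokens.base_order
    sgrna = "".join(order[t // 4] for t in tokens.indices)
    dna = "".join(order[t % 4] for t in tokens.indices)
    return sgrna, dna


def encode_dataset(pairs, base_order: str = DEFAULT_BASE_ORDER) -> np.ndarray:
    """Encode a collection of pairs into an (n, 23) integer index matrix."""
    out = np.empty((len(pairs), PAIR_LENGTH), dtype=np.int64)
    for row, pair in enumerate(pairs):
        try:
            out[row] = encode_pair(pair.sgrna_seq, pair.dna_seq, base_order).indices
        except ValueError as exc:
            raise ValueError(f"pair {row}: {exc}") from None
    return out


def match_tokens(base_order: str = DEFAULT_BASE_ORDER) -> frozenset[int]:
    """The 4 token values that represent a matched (b, b) position."""
    return frozenset(token_index(b, b, base_order) for b in base_order)


def mismatch_count(tokens: TokenSequence) -> int:
    """Number of mismatched positions: tokens outside the match subset."""
    matches = match_tokens(tokens.base_order)
    return int(sum(1 for t in tokens.indices if int(t) not in matches))
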