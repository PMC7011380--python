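"""CFD (Cutting Frequency Determination) baseline scoring.

CFD assigns each mismatch type at each protospacer position an activity
score in [0, 1]; the score of a candidate site is the product of the
entries for its mismatches (empty product = 1.0 for a perfect match).  For
example, an rG-dA mismatch at position 6 scoring 0.67 together with an
rC-dT mismatch at position 10 scoring 0.87 gives 0.67 x 0.87 = 0.583.

Conventions: positions are 1-based over the 20-nt protospacer counting from
the PAM-distal end (a ``pam_distal_first=False`` flag counts from the
PAM-proximal end instead); PAM positions 21-23 never contribute mismatches.
``rX-dY`` means sgRNA base X aligned against DNA base Y, both written in
the DNA alphabet.  The published full score table is distributed
separately; the loader below reads any per-mismatch table in the package's
4-column TSV layout (rna_base, dna_base, position, score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import PAIR_LENGTH

logger = logging.getLogger(__name__)

PROTOSPACER_LENGTH = 20

__all__ = ["CfdTable", "load_cfd_table", "save_cfd_table", "cfd_score", "score_dataset"]


@dataclass
class CfdTable:
    """Per-mismatch scores keyed by (rna_base, dna_base, position 1..20)."""

    entries: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (r, d, pos), score in self.entries.items():
            self._validate(r, d, pos, score)

    @staticmethod
    def _validate(r: str, d: str, pos: int, score: float) -> None:
        if r not in "ACGT" or d not in "ACGT":
            raise ValueError(f"bases must be A/C/G/T, got ({r!r}, {d!r})")
        if r == d:
            raise ValueError(f"({r}, {d}, {pos}) is a match, not a mismatch")
        if not 1 <= pos <= PROTOSPACER_LENGTH:
            raise ValueError(f"position {pos} outside 1..{PROTOSPACER_LENGTH}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1] for ({r}, {d}, {pos})")

    def add(self, rna_base: str, dna_base: str, position: int, score: float) -> None:
        self._validate(rna_base, dna_base, position, score)
        key = (rna_base, dna_base, position)
        if key in self.entries:
            raise ValueError(f"duplicate table entry for r{rna_base}-d{dna_base} "
                             f"at position {position}")
        self.entries[key] = score

    def get(self, rna_base: str, dna_base: str, position: int) -> float | None:
        return self.entries.get((rna_base, dna_base, position))

    def __len__(self) -> int:
        return len(self.entries)


def load_cfd_table(path) -> CfdTable:
    """Read a 4-column TSV (rna_base, dna_base, position, score)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CFD table not found: {path}")
    table = CfdTable()
    frame = pd.read_csv(path, sep="\t", dtype={"rna_base": str, "dna_base": str})
    for col in ("rna_base", "dna_base", "position", "score"):
        if col not in frame.columns:
            raise ValueError(f"CFD table missing column {col!r}")
    for row in frame.itertuples():
        table.add(str(row.rna_base).upper(), str(row.dna_base).upper(),
                  int(row.position), float(row.score))
    return table


def save_cfd_table(table: CfdTable, path) -> None:
    rows = [
        {"rna_base": r, "dna_base": d, "position": pos, "score": score}
        for (r, d, pos), score in sorted(table.entries.items())
    ]
    pd.DataFrame(rows, columns=["rna_base", "dna_base", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def cfd_score(
    sgrna_seq: str,
    dna_seq: str,
    table: CfdTable,
    strict: bool = True,
    pam_distal_first: bool = True,
) -> float:
    """Multiplicative CFD score of one aligned 23-nt pair.

    The product runs over mismatched protospacer positions only (PAM
    excluded); a perfect match scores 1.0.  In strict mode a mismatch
    absent from the table is an error; otherwise it scores 1.0 with a
    warning, so partial tables remain usable.
    """
    if len(sgrna_seq) != PAIR_LENGTH or len(dna_seq) != PAIR_LENGTH:
        raise ValueError(f"sequences must be {PAIR_LENGTH} nt")
    score = 1.0
    for i in range(PROTOSPACER_LENGTH):
        r, d = sgrna_seq[i], dna_seq[i]
        if r == d:
            continue
        position = i + 1 if pam_distal_first else PROTOSPACER_LENGTH - i
        entry = table.get(r, d, position)
        if entry is None:
            if strict:
                raise KeyError(
                    f"no table entry for mismatch r{r}-d{d} at protospacer "
                    f"position {position}"
                )
            logger.warning("mismatch r%s-d%s at position %s not in table; scoring 1.0",
                           r, d, position)
            entry = 1.0
        score *= entry
    return score


def score_dataset(data, table: CfdTable, strict: bool = True,
                  pam_distal_first: bool = True) -> np.ndarray:
    """CFD-score every pair of a dataset, in order."""
    return np.array(
        [cfd_score(p.sgrna_seq, p.dna_seq, table, strict, pam_distal_first) for p in data],
        dtype=np.float64,
    )
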