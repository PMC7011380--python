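"""Off-target tables, dataset container and splits.

The canonical on-disk format is a 6-column TSV with header
``sgrna_id  sgrna_seq  dna_seq  label  frequency  cell_line`` — one row per
candidate sgRNA-DNA site.  Real distributions of such tables vary in column
naming and order, so the reader accepts a column-mapping dialect.

Labeling semantics follow the screen data the method was designed for:
validated off-target sites carry label 1 and a positive measured cleavage
frequency; all other candidate loci carry label 0 and frequency 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import PAIR_LENGTH

CANONICAL_COLUMNS = ("sgrna_id", "sgrna_seq", "dna_seq", "label", "frequency", "cell_line")

__all__ = [
    "SgRnaDnaPair",
    "Dataset",
    "read_offtarget_table",
    "write_offtarget_table",
    "write_predictions",
    "read_predictions",
    "split_train_test",
    "export_sgrna_fasta",
    "CANONICAL_COLUMNS",
]


@dataclass(frozen=True)
class SgRnaDnaPair:
    """One candidate site: an sgRNA aligned against a 23-nt genomic locus."""

    sgrna_id: str
    sgrna_seq: str
    dna_seq: str
    label: int
    frequency: float
    cell_line: str = ""

    def __post_init__(self) -> None:
        for name in ("sgrna_seq", "dna_seq"):
            seq = getattr(self, name)
            if len(seq) != PAIR_LENGTH:
                raise ValueError(f"{name} must be {PAIR_LENGTH} nt, got {len(seq)}")
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"{name} contains non-ACGT character(s) {sorted(bad)}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0, 1], got {self.frequency}")
        if self.label == 1 and self.frequency <= 0.0:
            raise ValueError("label 1 requires a positive cleavage frequency")
        if self.label == 0 and self.frequency != 0.0:
            raise ValueError("label 0 requires frequency 0")


class Dataset:
    """Ordered collection of :class:`SgRnaDnaPair`, grouped by sgRNA id."""

    def __init__(self, pairs: Iterable[SgRnaDnaPair]):
        self.pairs: list[SgRnaDnaPair] = list(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SgRnaDnaPair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> SgRnaDnaPair:
        return self.pairs[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.pairs == other.pairs

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p.frequency for p in self.pairs], dtype=np.float64)

    @property
    def sgrna_ids(self) -> list[str]:
        return [p.sgrna_id for p in self.pairs]

    def unique_sgrna_ids(self) -> list[str]:
        """Distinct sgRNA ids in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.sgrna_id, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(self.pairs[int(i)] for i in indices)

    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": [p.sgrna_id for p in self.pairs],
                "sgrna_seq": [p.sgrna_seq for p in self.pairs],
                "dna_seq": [p.dna_seq for p in self.pairs],
                "label": [p.label for p in self.pairs],
                "frequency": [p.frequency for p in self.pairs],
                "cell_line": [p.cell_line for p in self.pairs],
            }
        )


def _row_error(row: int, message: str) -> ValueError:
    # row is the 0-based data-row index; report 1-based to the user
    return ValueError(f"row {row + 1}: {message}")


def read_offtarget_table(
    path,
    dialect: Mapping[str, str] | None = None,
    on_ambiguous: str = "error",
) -> Dataset:
    """Read an off-target table into a :class:`Dataset`.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Optional mapping from canonical column names (``sgrna_id`` ...) to
        the column names used in the file, for adapting third-party layouts
        without editing them.
    on_ambiguous
        ``"error"`` rejects rows whose sequences contain N or other
        ambiguity codes (the 16-token vocabulary covers A/C/G/T only);
        ``"skip"`` drops such rows silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"off-target table not found: {path}")
    if on_ambiguous not in ("error", "skip"):
        raise ValueError(f"on_ambiguous must be 'error' or 'skip', got {on_ambiguous!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = dict(dialect or {})
    missing = [
        mapping.get(col, col) for col in CANONICAL_COLUMNS[:5]
        if mapping.get(col, col) not in frame.columns
    ]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")

    def col(name: str, row: int, default: str | None = None) -> str:
        source = mapping.get(name, name)
        if source not in frame.columns:
            return default if default is not None else ""
        return str(frame.iloc[row][source])

    pairs: list[SgRnaDnaPair] = []
    for row in range(len(frame)):
        sgrna = col("sgrna_seq", row).strip().upper()
        dna = col("dna_seq", row).strip().upper()
        if on_ambiguous == "skip" and (set(sgrna + dna) - set("ACGT")):
            continue
        try:
            label = int(float(col("label", row)))
            frequency = float(col("frequency", row))
        except ValueError as exc:
            raise _row_error(row, f"malformed numeric field: {exc}") from None
        try:
            pairs.append(
                SgRnaDnaPair(
                    sgrna_id=col("sgrna_id", row),
                    sgrna_seq=sgrna,
                    dna_seq=dna,
                    label=label,
                    frequency=frequency,
                    cell_line=col("cell_line", row, default=""),
                )
            )
        except ValueError as exc:
            raise _row_error(row, str(exc)) from None
    return Dataset(pairs)


def write_offtarget_table(data: Dataset, path) -> None:
    """Write a dataset in the canonical 6-column TSV layout."""
    data.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_predictions(data: Dataset, scores, path) -> None:
    """Write the canonical columns plus a ``score`` column, one per pair."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(data),):
        raise ValueError(
            f"need one score per pair: {len(data)} pairs, {scores.shape} scores"
        )
    frame = data.to_frame()
    frame["score"] = scores
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path) -> tuple[Dataset, np.ndarray]:
    """Read back a predictions TSV written by :func:`write_predictions`."""
    frame = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str, "cell_line": str}, keep_default_na=False)
    scores = frame["score"].to_numpy(dtype=np.float64)
    pairs = [
        SgRnaDnaPair(
            sgrna_id=str(r.sgrna_id),
            sgrna_seq=r.sgrna_seq,
            dna_seq=r.dna_seq,
            label=int(r.label),
            frequency=float(r.frequency),
            cell_line=str(r.cell_line),
        )
        for r in frame.itertuples()
    ]
    return Dataset(pairs), scores


def split_train_test(
    data: Dataset,
    test_fraction: float,
    seed: int,
    stratify_by: str = "none",
) -> tuple[Dataset, Dataset]:
    """Random train/test partition, optionally stratified by cell line.

    Per stratum the test size is ``round(test_fraction * stratum size)``;
    the split is a disjoint, exhaustive partition and is deterministic for
    a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if len(data) == 0:
        raise ValueError("cannot split an empty dataset")
    if stratify_by not in ("none", "cell_line"):
        raise ValueError(f"stratify_by must be 'none' or 'cell_line', got {stratify_by!r}")

    rng = np.random.default_rng(seed)
    if stratify_by == "none":
        strata = {"": np.arange(len(data))}
    else:
        strata = {}
        for i, p in enumerate(data):
            strata.setdefault(p.cell_line, []).append(i)
        strata = {k: np.asarray(v) for k, v in sorted(strata.items())}

    test_idx: list[int] = []
    for name, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 pairs")
        n_test = int(round(test_fraction * len(idx)))
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(data)) if i not in test_set]
    return data.subset(train_idx), data.subset(sorted(test_idx))


def export_sgrna_fasta(data: Dataset, path) -> None:
    """Write the unique sgRNA sequences as FASTA (id = sgrna_id)."""
    seen: dict[str, str] = {}
    for p in data:
        seen.setdefault(p.sgrna_id, p.sgrna_seq)
    with open(path, "w") as handle:
        for name, seq in seen.items():
            handle.write(f">{name}\n{seq}\n")
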