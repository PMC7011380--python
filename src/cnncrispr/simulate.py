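"""Synthetic sgRNA/off-target benchmark generator.

Emulates the statistical structure of genome-wide off-target screens: a
handful of guides, thousands of candidate loci per guide differing from the
guide by 1-5 protospacer mismatches with an NGG PAM, and an extreme
negative:positive imbalance (default 250:1).

The planted cleavage propensity is multiplicative per mismatch: a hidden
position- and type-dependent score table (CFD-like) assigns each mismatch
an activity factor, and a site's latent propensity is the product over its
mismatches.  Positives are the top 1/(1 + ratio) fraction of sites by
propensity — guaranteeing the configured imbalance exactly — and their
recorded cleavage frequency is the propensity perturbed by truncated
Gaussian noise.  Because the signal is the only explicit mechanistic
scoring model in this problem domain, both the CFD baseline (with the
ground-truth table) and the network can in principle recover it, which is
what makes cross-module end-to-end checks meaningful.

All generation is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cfd import PROTOSPACER_LENGTH, CfdTable
from .data_io import Dataset, SgRnaDnaPair

BASES = "ACGT"
MIN_POSITIVE_FREQUENCY = 1e-6  # labels of 1 must carry a positive frequency

__all__ = [
    "GenerativeConfig",
    "generate_sgrnas",
    "generate_offtarget_sites",
    "random_propensity_table",
    "assign_ground_truth",
    "generate_dataset",
]


@dataclass
class GenerativeConfig:
    """Study-condition knobs for the generator.

    Defaults mirror the structure of the real screens this method targets:
    29 guides, candidate loci with 1-5 mismatches, ~250 negatives per
    positive, and mild measurement noise on positive frequencies.
    """

    n_sgrnas: int = 29
    sites_per_sgrna: int = 1000
    mismatch_min: int = 1
    mismatch_max: int = 5
    imbalance_ratio: float = 250.0
    noise_sd: float = 0.05
    seed: int = 0
    ground_truth_table: CfdTable | None = None
    cell_line: str = "synthetic"

    def __post_init__(self) -> None:
        if not 1 <= self.mismatch_min <= self.mismatch_max <= 5:
            raise ValueError("mismatch range must lie within [1, 5]")
        if self.imbalance_ratio <= 0:
            raise ValueError(f"imbalance_ratio must be > 0, got {self.imbalance_ratio}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_sgrnas(n: int, seed: int = 0) -> list[str]:
    """Uniform random 20-nt protospacers with an NGG PAM; distinct, seeded."""
    if n < 1:
        raise ValueError(f"need n >= 1 sgRNAs, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        protospacer = "".join(rng.choice(list(BASES), size=PROTOSPACER_LENGTH))
        seq = protospacer + rng.choice(list(BASES)) + "GG"
        if seq not in seen:  # collisions are ~4^-20 but regenerate anyway
            seen.add(seq)
            seqs.append(seq)
    return seqs


def generate_offtarget_sites(
    sgrna: str,
    n_sites: int,
    config: GenerativeConfig,
    sgrna_id: str = "sg0",
    seed: int | None = None,
) -> list[SgRnaDnaPair]:
    """Candidate loci for one guide: mutated copies with k mismatches.

    k is uniform on [mismatch_min, mismatch_max]; mismatch positions are
    uniform without replacement over the 20 protospacer positions; the
    substituted base is uniform over the 3 alternatives.  The PAM is
    preserved.  Pairs are returned unlabeled (label 0 placeholder).
    """
    if n_sites < 1:
        raise ValueError(f"need n_sites >= 1, got {n_sites}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 2])
    )
    pairs: list[SgRnaDnaPair] = []
    for _ in range(n_sites):
        k = int(rng.integers(config.mismatch_min, config.mismatch_max + 1))
        positions = rng.choice(PROTOSPACER_LENGTH, size=k, replace=False)
        dna = list(sgrna)
        for pos in positions:
            alternatives = [b for b in BASES if b != sgrna[pos]]
            dna[pos] = alternatives[int(rng.integers(3))]
        pairs.append(
            SgRnaDnaPair(
                sgrna_id=sgrna_id,
                sgrna_seq=sgrna,
                dna_seq="".join(dna),
                label=0,
                frequency=0.0,
                cell_line=config.cell_line,
            )
        )
    return pairs


def random_propensity_table(seed: int = 0, low: float = 0.05, high: float = 0.95) -> CfdTable:
    """A full hidden per-mismatch score table (12 types x 20 positions).

    Scores are uniform on [low, high], giving position- and type-dependent
    planted propensities with enough dynamic range to separate sites.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    table = CfdTable()
    for r in BASES:
        for d in BASES:
            if r == d:
                continue
            for pos in range(1, PROTOSPACER_LENGTH + 1):
                table.add(r, d, pos, float(rng.uniform(low, high)))
    return table


def assign_ground_truth(
    pairs: list[SgRnaDnaPair],
    config: GenerativeConfig,
    seed: int | None = None,
) -> Dataset:
    """Label pairs from their latent multiplicative propensity.

    The top 1/(1 + imbalance_ratio) fraction by propensity becomes positive
    with frequency = propensity + truncated Gaussian noise (sd =
    ``noise_sd``, clipped into (0, 1]); everything else is negative with
    frequency 0.  Exactly identical propensities are tie-broken by a seeded
    jitter so the rank cut is well defined.
    """
    from .cfd import cfd_score

    table = config.ground_truth_table
    if table is None:
        raise ValueError("config.ground_truth_table is required to assign labels")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 4])
    )
    propensity = np.array(
        [cfd_score(p.sgrna_seq, p.dna_seq, table, strict=True) for p in pairs]
    )
    if propensity.size and propensity.min() == propensity.max():
        propensity = propensity + rng.uniform(0, 1e-9, size=propensity.size)
    n_pos = int(round(len(pairs) / (1.0 + config.imbalance_ratio)))
    order = np.argsort(-propensity, kind="stable")
    positive = np.zeros(len(pairs), dtype=bool)
    positive[order[:n_pos]] = True
    labeled: list[SgRnaDnaPair] = []
    for i, pair in enumerate(pairs):
        if positive[i]:
            freq = propensity[i] + rng.normal(0.0, config.noise_sd) if config.noise_sd else propensity[i]
            freq = float(np.clip(freq, MIN_POSITIVE_FREQUENCY, 1.0))
            labeled.append(replace(pair, label=1, frequency=freq))
        else:
            labeled.append(replace(pair, label=0, frequency=0.0))
    return Dataset(labeled)


def generate_dataset(config: GenerativeConfig) -> tuple[Dataset, CfdTable]:
    """Full benchmark: guides, candidate sites, planted labels.

    Labels are assigned per guide, so positives spread across guides and
    every guide attains the configured imbalance.  Returns the dataset and
    the hidden propensity table (the oracle for near-perfect CFD scoring).
    """
    table = config.ground_truth_table or random_propensity_table(config.seed)
    config = replace(config, ground_truth_table=table)
    sgrnas = generate_sgrnas(config.n_sgrnas, seed=config.seed)
    all_pairs: list[SgRnaDnaPair] = []
    for g, sgrna in enumerate(sgrnas):
        sites = generate_offtarget_sites(
            sgrna, config.sites_per_sgrna, config, sgrna_id=f"sg{g:02d}",
            seed=config.seed + 1000 + g,
        )
        labeled = assign_ground_truth(sites, config, seed=config.seed + 2000 + g)
        all_pairs.extend(labeled)
    return Dataset(all_pairs), table
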