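import numpy as np
import pytest

from cnncrispr.cfd import CfdTable
from cnncrispr.data_io import Dataset, SgRnaDnaPair
from cnncrispr.simulate import GenerativeConfig, generate_dataset, random_propensity_table


def make_pair(sgrna="ACGTACGTACGTACGTACGTAGG", dna=None, label=0, freq=0.0,
              sgrna_id="sg0", cell_line="hek"):
    return SgRnaDnaPair(sgrna_id=sgrna_id, sgrna_seq=sgrna, dna_seq=dna or sgrna,
                        label=label, frequency=freq, cell_line=cell_line)


@pytest.fixture
def tiny_dataset():
    """3 pairs from 2 guides: one validated off-target site, two negatives."""
    g1 = "ACGTACGTACGTACGTACGTAGG"
    g2 = "TTTTCCCCGGGGAAAATTTTCGG"
    d1 = "ACGTACGAACGTACGTACGTAGG"  # one mismatch at position 8
    return Dataset([
        make_pair(g1, d1, label=1, freq=0.4, sgrna_id="sgA"),
        make_pair(g1, g1, label=0, sgrna_id="sgA"),
        make_pair(g2, g2, label=0, sgrna_id="sgB", cell_line="k562"),
    ])


@pytest.fixture(scope="session")
def small_benchmark():
    """Seeded synthetic benchmark: 4 guides x 300 sites, 20:1 imbalance."""
    config = GenerativeConfig(n_sgrnas=4, sites_per_sgrna=300, imbalance_ratio=20.0,
                              noise_sd=0.0, seed=7)
    data, table = generate_dataset(config)
    return data, table


@pytest.fixture
def paper_cfd_table():
    """The two per-mismatch entries of the published worked example."""
    table = CfdTable()
    table.add("G", "A", 6, 0.67)
    table.add("C", "T", 10, 0.87)
    return table
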