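import numpy as np
import pandas as pd
import pytest

from pmdscape import simulate as sim
from pmdscape.core_io import GenomeSpec, Methylome, SegmentSet


@pytest.fixture(scope="session")
def small_truth():
    """10 Mb single-chromosome planted state map shared across tests."""
    cfg = sim.SimConfig(seed=5, chrom_lengths={"chr1": 10_000_000})
    return cfg, sim.simulate_state_map(cfg)


@pytest.fixture(scope="session")
def small_methylome(small_truth):
    cfg, truth = small_truth
    return sim.simulate_methylome(truth, cfg, group=0, seed=11)


@pytest.fixture
def toy_methylome():
    """Hand-written five-CpG methylome on two chromosomes."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3 + ["chr2"] * 2,
            "pos": [100, 150, 220, 50, 90],
            "strand": ["+"] * 5,
            "coverage": [10, 30, 20, 5, 8],
            "methylated": [5, 30, 10, 0, 8],
        }
    )
    return Methylome(df, "toy")


@pytest.fixture
def genome_2chr():
    return GenomeSpec({"chr1": 2_500, "chr2": 1_000, "chrX": 5_000})


def make_segments(rows):
    return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
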