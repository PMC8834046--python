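import numpy as np
import pandas as pd
import pytest

from ginscore.seg import Segment, SegmentProfile
from ginscore.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, sample_id="S1", n_segments=50, chroms=("chr1", "chr2", "chr3")):
    """A valid random segment profile (abutting segments per chromosome)."""
    segments = []
    for chrom in chroms:
        pos = 0
        for _ in range(max(1, n_segments // len(chroms))):
            length = int(rng.integers(100, 5_000_000))
            segments.append(Segment(chrom, pos, pos + length, float(rng.normal(0, 0.4))))
            pos += length
    return SegmentProfile(sample_id, segments)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-mostly tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=60, n_genes=300, n_planted=15, seed=11)
    )


@pytest.fixture
def toy_expr():
    return pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 4.0],
            "s2": [4.0, 3.0, 2.0, 1.0],
            "s3": [2.0, 4.0, 1.0, 3.0],
        },
        index=pd.Index(["GA", "GB", "GC", "GD"], name="gene_id"),
    )
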