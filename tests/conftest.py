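import numpy as np
import pytest

from accessmask import PileupTrack, Reference, make_reference, simulate_pileup
from accessmask.simulate import PlantedRegion, SimConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Fast 70 kb cohort with one planted region of each detectable kind."""
    return SimConfig(
        chromosomes={"chr1": 30_000, "chr2": 20_000, "chrX": 12_000, "chrY": 8_000},
        sample_count=4,
        per_sample_mean_depth=5.0,
        read_length=50,
        seed=11,
        regions=(
            PlantedRegion("chr1", 5_000, 7_000, "n_gap"),
            PlantedRegion("chr1", 12_000, 14_000, "low_coverage"),
            PlantedRegion("chr1", 20_000, 22_000, "high_coverage"),
            PlantedRegion("chr2", 4_000, 6_000, "repeat_mq0"),
        ),
    )


@pytest.fixture(scope="session")
def tiny_reference(tiny_config) -> Reference:
    return make_reference(tiny_config)


@pytest.fixture(scope="session")
def tiny_pileup(tiny_config, tiny_reference):
    return simulate_pileup(tiny_config, tiny_reference)


def random_track(rng: np.random.Generator, lengths, max_depth: int = 200):
    """Random but invariant-respecting PileupTrack."""
    t = PileupTrack.zeros(lengths)
    for chrom, n in lengths.items():
        depth = rng.integers(0, max_depth, size=n)
        mq0 = rng.binomial(depth, rng.uniform(0, 0.4))
        mq_sum = rng.integers(0, 60 * np.maximum(depth - mq0, 0) + 1)
        t.depth[chrom] = depth.astype(np.int64)
        t.mq0[chrom] = mq0.astype(np.int64)
        t.mq_sum[chrom] = mq_sum.astype(np.int64)
    return t
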