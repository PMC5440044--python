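import numpy as np
import pytest

from replitime.binning import BinnedGenome, CountTrack
from replitime.simulate import SimOrigin, SimulationConfig


@pytest.fixture
def small_genome():
    return BinnedGenome([("chrA", 30_000), ("chrB", 15_300)], 300)


@pytest.fixture
def two_origin_config():
    """100-kb chromosome with an early and a late origin."""
    return SimulationConfig(
        chromosomes=[("chr", 100_000)],
        origins=[
            SimOrigin("chr", 30_000, mean_firing_time=20.0, firing_sd=5.0),
            SimOrigin("chr", 70_000, mean_firing_time=40.0, firing_sd=5.0),
        ],
        timepoints=[20.0, 30.0, 40.0, 50.0, 150.0],
        fork_speed_kb_min=1.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(genome, counts, **kw):
    return CountTrack(genome, np.asarray(counts), **kw)
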