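import numpy as np
import pytest

from rrbsqc import (
    AlignStatus,
    SimConfig,
    align_reads,
    build_index,
    rrbs_target_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_genome():
    """20 kb RRBS-like genome shared across fast tests."""
    return rrbs_target_genome(20_000, seed=42)


@pytest.fixture(scope="session")
def sim(small_genome):
    """Default-condition library simulation on the small genome."""
    return simulate_library(small_genome, SimConfig(seed=7, depth=20.0))


@pytest.fixture(scope="session")
def sim_clean(small_genome):
    """Error-free simulation: no conversion failure, no sequencing error."""
    return simulate_library(
        small_genome,
        SimConfig(seed=7, depth=10.0, conversion_failure=0.0, seq_error_rate=0.0),
    )


@pytest.fixture(scope="session")
def aligned(sim, small_genome):
    """Unique alignments of the default simulation."""
    index = build_index(small_genome)
    out = align_reads(sim.reads, index, small_genome)
    return [a for a in out if a.status is AlignStatus.UNIQUE]
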