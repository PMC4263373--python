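import numpy as np
import pytest

from phasitrack.srio import AlignmentRecord, Library
from phasitrack.synthetic_data import (
    GeneratorConfig,
    make_genome,
    make_libraries,
    simulate_pare,
    simulate_reads,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Full synthetic dataset at default study conditions, seed 0."""
    genome, truth = make_genome(default_config)
    reads = simulate_reads(truth, default_config)
    tags = simulate_pare(truth, default_config)
    libraries = make_libraries(default_config)
    return {
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "tags": tags,
        "libraries": libraries,
    }


@pytest.fixture
def lib():
    return Library("wt_1", "wildtype", 1, 1_000_000)


def make_records(positions, chrom="chr1", length=21, strand="+", copies=1):
    return [
        AlignmentRecord(chrom, p, length, strand, copies=copies) for p in positions
    ]


@pytest.fixture
def records_factory():
    return make_records
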