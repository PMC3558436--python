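import numpy as np
import pytest

from nanochromkit import simgenome


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated genome shared by read-only tests."""
    params = simgenome.SimParams(
        n_loci=40,
        seed=11,
        coverage_x=30.0,
        altfrag_fraction=0.25,
        telo_read_depth=30.0,
    )
    truth, contigs = simgenome.simulate_genome(params)
    reads = simgenome.simulate_reads(truth, params)
    return params, truth, contigs, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
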