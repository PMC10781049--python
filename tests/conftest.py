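import numpy as np
import pytest

from introtrace.simulate import StudyConfig, simulate_study
from introtrace.simulate.meiosis import ChromosomeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One default simulated study (seed 1), shared across tests."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(StudyConfig(), outdir, seed=1)


@pytest.fixture
def one_chrom():
    return ChromosomeSpec("chr1", 1_000_000, 100.0)
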