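import numpy as np
import pytest

from milseq import pipeline
from milseq.synth import TruthParams
from milseq.types import CoverageTrack


@pytest.fixture(scope="session")
def default_params():
    return TruthParams(seed=7)


@pytest.fixture(scope="session")
def dataset(default_params):
    """One simulated dataset at the default study conditions, shared read-only."""
    return pipeline.simulate_dataset(default_params)


@pytest.fixture(scope="session")
def mil_results(dataset):
    mils, peaks = pipeline.mil_pipeline(
        dataset["genes"], dataset["l1s"], dataset["tracks"]
    )
    return mils, peaks


def make_track(assay, strand, chrom, segments, library_size, chroms=None):
    """Build a CoverageTrack from (start, end, value) triples on one chromosome."""
    s, e, v = (np.array(x) for x in zip(*segments))
    return CoverageTrack(assay, strand, {chrom: (s, e, v)}, library_size, chroms)


@pytest.fixture
def uniform_track():
    return make_track("TT", "+", "chr1", [(0, 200_000, 2.0)], 1_000_000)
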