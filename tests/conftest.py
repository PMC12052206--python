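import numpy as np
import pytest
from hypothesis import settings

from k27domains import BinGrid, CoverageTrack

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_track(values, bin_width=100, chrom="chr1", smoothed=False, **kwargs):
    """CoverageTrack on a single chromosome from a flat list of bin values."""
    values = np.asarray(values, dtype=float)
    grid = BinGrid({chrom: len(values) * bin_width}, bin_width=bin_width)
    return CoverageTrack(grid=grid, values={chrom: values}, smoothed=smoothed, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
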