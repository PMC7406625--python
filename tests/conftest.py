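import numpy as np
import pytest

from dormqtl.binmap import WindowBinCaller
from dormqtl.pipeline import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """Tiny simulated BIL population (2 chromosomes, 60 markers, 40 lines)."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_bins(tiny):
    """Fitted bin caller for the tiny population."""
    return WindowBinCaller().fit(tiny.snp, chrom_lengths=tiny.gmap.lengths_bp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
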