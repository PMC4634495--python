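import numpy as np
import pytest

from aecopd.preprocess import FilterSpec, design_bandpass


@pytest.fixture()
def rng():
    """A fresh seeded generator per test, so tests are order-independent."""
    return np.random.default_rng(20150)


@pytest.fixture(scope="session")
def bp_taps():
    """The default 100-2000 Hz equiripple filter, designed once per session."""
    return design_bandpass(FilterSpec(), 8000)
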