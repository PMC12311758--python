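import numpy as np
import pytest

from eegcrit.spectral import make_bank, transform


@pytest.fixture(scope="session")
def bank512():
    return make_bank(512.0)


@pytest.fixture(scope="session")
def wavelet_envelope(bank512):
    """Extract the valid-sample envelope at the bank frequency nearest ``freq``."""

    def _extract(rec, freq=8.0):
        k = bank512.nearest_index(freq)
        d = transform(rec, bank512, freq_indices=[k])
        return d.envelope[0, 0][d.valid_mask[0]], bank512.freqs[k]

    return _extract


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
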