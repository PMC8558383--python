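import logging

import numpy as np
import pytest

from thzfb import spectra, synthetic

# BEADS logs a warning when the MM budget runs out on hard rows; keep
# test output readable.
logging.getLogger("thzfb.baselines").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A 12+12 sample synthetic dataset shared by read-only tests."""
    return synthetic.generate_dataset(12, 12, seed=42)


@pytest.fixture(scope="session")
def small_band_spectra(small_dataset):
    dataset, _ = small_dataset
    return spectra.band_select(spectra.fft_dataset(dataset), 0.3, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
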