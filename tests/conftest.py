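import numpy as np
import pytest

from resbind.datamodel import ProteinRecord, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A narrow configuration that keeps network tests fast."""
    return RunConfig(d_hid=16, n_heads=4, d_ff=32, n_enc_layers=2, n_dec_layers=2,
                     window_size=7, dropout_rate=0.0, seed=3)


@pytest.fixture
def toy_protein():
    return ProteinRecord("toy1", "MKVLINGKTLKGEITVDGAKNAVLPIL")
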