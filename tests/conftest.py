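import numpy as np
import pytest

from thermorca.encoding import encode
from thermorca.synthetic import make_planted_dataset
from thermorca.vae import VaeConfig, train_unsupervised


@pytest.fixture(scope="session")
def planted_small():
    """Small planted dataset shared across unit tests: 60 seqs, 60 columns."""
    return make_planted_dataset(n_seqs=60, length=60, seed=11)


@pytest.fixture(scope="session")
def small_unsup_model(planted_small):
    """An unsupervised VAE trained briefly on the small planted MSA."""
    msa, _ = planted_small
    cfg = VaeConfig(encoder_widths=(64, 32), decoder_widths=(32, 64), epochs=80, seed=11)
    return train_unsupervised(encode(msa), cfg)
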