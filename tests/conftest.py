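import numpy as np
import pytest

from simvae import chem, codec, data
from simvae.codec import build_vocab
from simvae.model import SmilesVae, VaeConfig


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic paired dataset shared by fast unit tests."""
    return data.generate_synthetic_dataset(60, seed=7)


@pytest.fixture(scope="session")
def small_vocab(small_dataset):
    return build_vocab(small_dataset.pool)


@pytest.fixture()
def tiny_model(small_vocab):
    return SmilesVae(
        small_vocab,
        VaeConfig(latent_dim=8, hidden_size=16, embed_size=8, max_len=40, seed=3),
    )


@pytest.fixture(scope="session")
def fingerprint_pool(small_dataset):
    return {s: chem.morgan_fingerprint(s) for s in small_dataset.pool}


@pytest.fixture(scope="session")
def study_result():
    """Full desk-scale study: metric phase, ablation arm, RL fine-tuning.

    Trained once per session; several end-to-end checks read from it.
    """
    from simvae.workflow import run_study

    return run_study(seed=11)
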