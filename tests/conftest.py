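import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import targen as tg
from targen.training import PretrainConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def corpus300():
    """Small synthetic pre-training corpus shared across the suite."""
    return tg.generate_corpus(n=300, seed=7)


@pytest.fixture(scope="session")
def vocab300(corpus300):
    return tg.build_vocabulary(list(corpus300.records["selfies"]))


@pytest.fixture(scope="session")
def tiny_cfg(vocab300):
    return tg.ModelConfig(vocab_size=len(vocab300), d_model=32, n_heads=2,
                          n_blocks=3, adapter_dim=8, max_len=48, dropout=0.1)


@pytest.fixture(scope="session")
def pretrained_tiny(corpus300, vocab300, tiny_cfg):
    """A briefly pre-trained unconditional model (session-scoped; clone
    before mutating)."""
    model = tg.ConditionalDecoder(tiny_cfg, seed=0)
    train = corpus300.records[corpus300.records["split"] == "train"]
    tg.pretrain(model, train, vocab300,
                PretrainConfig(epochs=2, batch_size=64), seed=1)
    return model


@pytest.fixture(scope="session")
def target_sets():
    return tg.generate_target_sets(seed=11)


@pytest.fixture
def clone():
    def _clone(model: tg.ConditionalDecoder) -> tg.ConditionalDecoder:
        twin = tg.ConditionalDecoder(model.config, _init=False)
        twin.params = {}
        for name, p in model.params.items():
            twin._add(name, p.data.copy())
        twin.adapter_blocks = model.adapter_blocks
        return twin
    return _clone


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
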