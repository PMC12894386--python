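import numpy as np
import pytest
from hypothesis import settings

import lightwavenet as lwn
from lightwavenet.network import LightWaveNet, NetConfig
from lightwavenet.supervision import LossConfig, TrainConfig, train

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# a deliberately small architecture for fast tests (stage widths 16/8 -> 16)
MICRO = NetConfig(
    num_classes=4,
    stem_channels=8,
    growth_rate=8,
    wpm_per_stage=(1, 1, 1, 1),
    input_size=64,
)


@pytest.fixture(scope="session")
def micro_config() -> NetConfig:
    return MICRO


@pytest.fixture(scope="session")
def synth_records():
    return lwn.generate_synthetic_dataset(
        lwn.default_class_specs(4), per_class=12, size=64, seed=123
    )


@pytest.fixture(scope="session")
def synth_split(synth_records):
    return lwn.stratified_split(synth_records, (5, 1, 4), seed=0)


@pytest.fixture(scope="session")
def trained_micro(synth_split):
    model = LightWaveNet(MICRO, seed=0)
    train(model, synth_split, TrainConfig(epochs=2, batch_size=16), LossConfig(), seed=0)
    return model
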