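import numpy as np
import pytest

import esdflow as ef
from esdflow.attention import HeadConfig
from esdflow.encoder import EncoderConfig
from esdflow.tcn import TcnConfig

SMALL_APP = ef.AppearanceConfig(height=32, width=32)


@pytest.fixture(scope="session")
def small_cases():
    """Six synthetic cases at 32x32, 1 fps — shared read-only fixture."""
    return ef.make_dataset(6, duration_s=300.0, fps=1.0,
                           appearance=SMALL_APP, seed=11)


@pytest.fixture(scope="session")
def small_configs():
    enc = EncoderConfig(embedding_dim=32, input_hw=(32, 32))
    tcn = TcnConfig(num_layers=7, channels=32, input_dim=32)
    head = HeadConfig(window=30, query_dim=32, channels=32)
    return enc, tcn, head


@pytest.fixture(scope="session")
def trained_bundle(small_cases, small_configs):
    """A quickly trained end-to-end model shared by inference-level tests."""
    from esdflow.training import StageSchedule, TrainSchedule, train_full

    enc, tcn, head = small_configs
    schedule = TrainSchedule(
        stage1=StageSchedule(160, 5e-3, (120,), 10.0, 32),
        stage2=StageSchedule(100, 1e-3, (70, 90), 10.0),
    )
    bundle, history = train_full(small_cases, enc, tcn, head, schedule, seed=7)
    return bundle, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
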