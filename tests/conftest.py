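import numpy as np
import pytest

import sobelnet as sn


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_epochs():
    """Small separable cohort: 9 channels at 32 Hz keeps the network tiny."""
    recs = sn.generate_dataset(
        (3, 3), seed=5, duration_s=48.0, sampling_rate=32.0, n_channels=12,
        effect_size=3.0,
    )
    return sn.dataset_epochs(recs, window_s=4.0, stride_s=2.0)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return sn.TrainConfig(seed=5, n_epochs=6, batch_size=8, nf=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_epochs, tiny_train_cfg):
    params, curve = sn.train(tiny_epochs, tiny_train_cfg)
    return params, curve
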