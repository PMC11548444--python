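import numpy as np
import pytest

from mdar import MDARConfig, SyntheticConfig, generate_dataset
from mdar.preprocessing import PreprocessConfig, preprocess_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net_config():
    """Smallest legal network: 16x16 input, 12-wide stages, short chunks."""
    return MDARConfig(
        stage_widths=(12, 12, 12, 12, 12, 12), chunk_len=60, image_size=16
    )


@pytest.fixture(scope="session")
def tiny_synth_config():
    """Small frames so generation stays fast in unit tests."""
    return SyntheticConfig(height=16, width=16, duration_s=4.0)


@pytest.fixture(scope="session")
def tiny_chunks(tiny_synth_config):
    samples = generate_dataset(6, tiny_synth_config, seed=7)
    pp = PreprocessConfig(chunk_len=60, target_size=16)
    return preprocess_dataset(samples, pp)
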