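import numpy as np
import pytest

from ictalnet.model import PINConfig
from ictalnet.preprocess import preprocess_dataset
from ictalnet.synthetic import SynthSpec, generate_dataset

# tiny profile shared by the training/evaluation tests: short signals,
# small windows and scale counts so every network fit takes well under a
# second while exercising every stage
TINY_WINDOW = 32
TINY_SCALES = 8
TINY_N_SAMPLES = 128


@pytest.fixture(scope="session")
def tiny_records():
    spec = SynthSpec(n_per_class=6, n_samples=TINY_N_SAMPLES, seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_stacks(tiny_records):
    return preprocess_dataset(
        tiny_records,
        window_len=TINY_WINDOW,
        overlap=0.0,
        wavelet="morlet",
        n_scales=TINY_SCALES,
    )


@pytest.fixture(scope="session")
def tiny_config(tiny_stacks):
    s, w, n = tiny_stacks[0].tensor.shape
    return PINConfig(n_blocks=n, input_scales=s, input_width=w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
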