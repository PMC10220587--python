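import numpy as np
import pytest

from pafnet.model import NetworkSpec
from pafnet.records import SynthConfig, generate_record


@pytest.fixture(scope="session")
def nsr_record():
    """Clean all-sinus record, 150 beats."""
    return generate_record(SynthConfig(rhythm_plan=[("NSR", 150)], seed=42))


@pytest.fixture(scope="session")
def af_record():
    """Clean all-AF record, 150 beats."""
    return generate_record(SynthConfig(rhythm_plan=[("AF", 150)], seed=43))


@pytest.fixture(scope="session")
def paroxysmal_record():
    """NSR / AF / NSR plan with one 30-beat episode."""
    return generate_record(SynthConfig(
        rhythm_plan=[("NSR", 50), ("AF", 30), ("NSR", 40)], seed=44))


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature but structurally complete network, for fast tests."""
    return NetworkSpec(input_length=60, kernel_size=5, n_blocks=4,
                       filters_initial=4, filters_double_at_block=3,
                       d_model=8, n_heads=2, ffn_hidden=6, pos_table_len=20,
                       head_hidden=6, dropout_rate=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
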