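import logging

import numpy as np
import pytest

from attentrf.simulate import (
    ConditionSpec,
    EEGSimSpec,
    SimConfig,
    gen_dataset,
)

# crossfade-truncation warnings are expected whenever the switch duration
# exceeds the window spacing; keep test output readable
logging.getLogger("attentrf.inference").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def micro_config(**overrides) -> SimConfig:
    """A deliberately tiny simulation for plumbing tests (not study scale)."""
    defaults = dict(
        n_subjects=2,
        n_trials_per_condition=3,
        trial_duration_range_s=(11.0, 11.0),
        conditions=(
            ConditionSpec("easy", 0.0, 0.0),
            ConditionSpec("difficult", 0.10, 0.2),
        ),
        eeg=EEGSimSpec(n_channels=6, snr=0.5),
        master_seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def micro_dataset():
    return gen_dataset(micro_config())
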