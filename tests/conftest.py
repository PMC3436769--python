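import numpy as np
import pytest

from eogstage.config import StagerConfig
from eogstage.io import Hypnogram, RawChannel, derive_staging_signal
from eogstage.stager import prepare_signal, stage_record
from eogstage.synthetic import (
    SDB_PROFILES,
    SynthesisParams,
    profile_to_model,
    simulate_hypnogram,
    simulate_respiratory_events,
    synthesize_signal,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_record():
    """A seeded 120-epoch high-contrast record with truth labels."""
    profile = SDB_PROFILES["normal"]
    hyp = simulate_hypnogram(profile_to_model(profile, n_epochs=120, seed=7))
    events = simulate_respiratory_events(hyp, profile, seed=8)
    left, right = synthesize_signal(
        hyp, SynthesisParams.high_contrast(), events=events, seed=9
    )
    return hyp, events, left, right


@pytest.fixture(scope="session")
def staged_small_record(small_record):
    hyp, events, left, right = small_record
    config = StagerConfig()
    epoched = prepare_signal(derive_staging_signal(left, right), config)
    auto, decisions, features = stage_record(epoched, config)
    return hyp, auto, decisions, features


def make_channel(samples, rate=128.0, label="X"):
    return RawChannel(label=label, sampling_rate=rate, samples=np.asarray(samples, float))


@pytest.fixture
def hypnogram_factory():
    def make(stages, epoch_length=30.0):
        return Hypnogram(stages=list(stages), epoch_length=epoch_length)

    return make
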