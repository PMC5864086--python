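import numpy as np
import pytest

from speechtrack import CANONICAL_BANDS, SynthConfig, generate_corpus, generate_participant
from speechtrack.tracking import prepare_trials


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Small but fully structured dataset: 2x2x2 grid, one effect point."""
    return SynthConfig(
        n_sentences=20,
        n_trials=16,
        n_participants=2,
        grid_shape=(2, 2, 2),
        effect_region=np.array([1]),
        pac_region=np.array([1]),
        tracking_snr_correct=0.8,
        tracking_snr_incorrect=0.8,
        pac_depth_correct=0.8,
        pac_depth_incorrect=0.8,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def corpus(small_cfg):
    return generate_corpus(small_cfg)


@pytest.fixture(scope="session")
def participant_raw(small_cfg, corpus):
    _, envelopes = corpus
    return generate_participant(small_cfg, envelopes, participant=0)


@pytest.fixture(scope="session")
def phrase_trials(participant_raw):
    return prepare_trials(participant_raw, CANONICAL_BANDS["phrase"])


@pytest.fixture(scope="session")
def phoneme_trials(participant_raw):
    return prepare_trials(participant_raw, CANONICAL_BANDS["phoneme"])
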