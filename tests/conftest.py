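import numpy as np
import pytest

import p300fuse as pf
from p300fuse.synth import SubjectProfile


@pytest.fixture(scope="session")
def tiny_paradigm():
    """Two characters, three rounds: 72 flashes, 12 targets."""
    return pf.SpellerParadigm(n_characters=2, n_repetitions=3)


@pytest.fixture(scope="session")
def noiseless_profile():
    """Deterministic subject: no noise, no latency jitter."""
    return SubjectProfile(p300_amplitude=8.0, p300_latency=0.300,
                          latency_jitter_sd=0.0, noise_scale=0.0)


@pytest.fixture(scope="session")
def small_session(tiny_paradigm):
    """Two-subject moderate-SNR session on the tiny paradigm."""
    return pf.generate_session(pf.SynthConfig(
        paradigm=tiny_paradigm, n_subjects=2, snr_preset="moderate", seed=7))


@pytest.fixture(scope="session")
def small_epoch_sets(small_session):
    """Preprocessed, aligned epoch sets for the two small-session subjects."""
    return [
        pf.preprocess_session(sig, small_session.sampling_rate,
                              small_session.events, epoch_samples=144,
                              downsample_factor=2, subject_id=f"S{i + 1}",
                              channel_labels=small_session.channel_labels)
        for i, sig in enumerate(small_session.signals)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
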