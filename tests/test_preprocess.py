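"""Filtering, epoching, decimation and z-scoring."""

import numpy as np
import pytest

import p300fuse as pf
from p300fuse.errors import ConfigurationError, DomainError
from p300fuse.paradigm import StimulusEvent
from p300fuse.preprocess import FilterSettings


def _tone(freq, rate=240.0, seconds=10.0, n_channels=2):
    t = np.arange(int(seconds * rate)) / rate
    return np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_channels))


def _mid_rms(x):
    n = x.shape[0]
    return np.sqrt(np.mean(x[n // 4: 3 * n // 4] ** 2))


class TestFilterSignal:
    def test_50hz_tone_attenuated_40db(self):
        x = _tone(50.0)
        y = pf.filter_signal(x, 240.0)
        assert _mid_rms(y) < 0.01 * _mid_rms(x)          # >= 40 dB down

    def test_10hz_tone_passes_within_half_db(self):
        x = _tone(10.0)
        y = pf.filter_signal(x, 240.0)
        ratio = _mid_rms(y) / _mid_rms(x)
        assert abs(20 * np.log10(ratio)) < 0.5

    def test_zero_signal_stays_zero(self):
        y = pf.filter_signal(np.zeros((2400, 3)), 240.0)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_zero_phase_preserves_peak_latency(self):
        # a smooth bump at a known sample should not shift
        t = np.arange(2400) / 240.0
        x = np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)[:, None]
        y = pf.filter_signal(x, 240.0)
        assert abs(int(np.argmax(y[:, 0])) - int(np.argmax(x[:, 0]))) <= 2

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="Nyquist"):
            pf.filter_signal(np.zeros((100, 1)), 50.0,
                             FilterSettings(bandpass_high=30.0))


def _events_at(onsets, targets=None):
    return [StimulusEvent(onset_sample=o, code=1 + (i % 12),
                          is_target=bool(targets[i]) if targets else False,
                          character_index=0, repetition_index=0)
            for i, o in enumerate(onsets)]


class TestExtractEpochs:
    def test_window_is_signal_slice(self, rng):
        signal = rng.standard_normal((800, 3))
        es = pf.extract_epochs(signal, 240.0, _events_at([0]), 702)
        np.testing.assert_array_equal(es.data[0], signal[:702])

    def test_overrunning_events_dropped(self, rng):
        signal = rng.standard_normal((500, 2))
        es = pf.extract_epochs(signal, 240.0, _events_at([0, 100, 450]), 100)
        assert es.n_epochs == 2

    def test_labels_copied_from_targets(self, rng):
        signal = rng.standard_normal((400, 2))
        es = pf.extract_epochs(signal, 240.0,
                               _events_at([0, 50, 100], targets=[1, 0, 1]), 50)
        np.testing.assert_array_equal(es.labels, [True, False, True])

    def test_empty_events_rejected(self):
        with pytest.raises(DomainError):
            pf.extract_epochs(np.zeros((100, 2)), 240.0, [], 10)


class TestDownsample:
    def test_702_to_351_at_120hz(self, rng):
        es = pf.EpochSet(data=rng.standard_normal((3, 702, 8)),
                         labels=np.zeros(3, bool), sampling_rate=240.0)
        out = pf.downsample(es, 2)
        assert out.data.shape == (3, 351, 8)
        assert out.sampling_rate == 120.0

    def test_index_selection_definition(self):
        es = pf.EpochSet(data=np.arange(6, dtype=float).reshape(1, 6, 1),
                         labels=np.zeros(1, bool), sampling_rate=240.0)
        np.testing.assert_array_equal(pf.downsample(es, 2).data[:, :, 0],
                                      [[0, 2, 4]])
        # odd length: floor(7/2) = 3 points kept
        es7 = pf.EpochSet(data=np.arange(7, dtype=float).reshape(1, 7, 1),
                          labels=np.zeros(1, bool), sampling_rate=240.0)
        assert pf.downsample(es7, 2).n_time == 3

    def test_factor_one_is_identity(self, rng):
        es = pf.EpochSet(data=rng.standard_normal((2, 10, 2)),
                         labels=np.zeros(2, bool), sampling_rate=240.0)
        np.testing.assert_array_equal(pf.downsample(es, 1).data, es.data)

    def test_bad_factor_rejected(self):
        es = pf.EpochSet(data=np.zeros((1, 4, 1)), labels=np.zeros(1, bool),
                         sampling_rate=240.0)
        with pytest.raises(DomainError):
            pf.downsample(es, 0)


class TestZScore:
    def test_unit_stats_per_channel(self, rng):
        es = pf.EpochSet(data=rng.standard_normal((5, 100, 4)) * 7 + 3,
                         labels=np.zeros(5, bool), sampling_rate=120.0)
        out, stats = pf.zscore_normalize(es)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=0), 1.0, atol=1e-9)
        assert out.normalized
        np.testing.assert_allclose(stats.mean, es.data.mean(axis=1))

    def test_hand_computed_case(self):
        es = pf.EpochSet(data=np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1),
                         labels=np.zeros(1, bool), sampling_rate=120.0)
        out, _ = pf.zscore_normalize(es)
        np.testing.assert_allclose(out.data[0, :, 0],
                                   [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_channel_becomes_zero(self):
        data = np.stack([np.full((10,), 5.0), np.arange(10.0)], axis=1)[None]
        es = pf.EpochSet(data=data, labels=np.zeros(1, bool), sampling_rate=120.0)
        out, stats = pf.zscore_normalize(es)
        np.testing.assert_array_equal(out.data[0, :, 0], 0.0)
        assert stats.std[0, 0] == 0.0

    def test_double_normalization_rejected_but_idempotent_values(self, rng):
        es = pf.EpochSet(data=rng.standard_normal((2, 50, 2)),
                         labels=np.zeros(2, bool), sampling_rate=120.0)
        once, _ = pf.zscore_normalize(es)
        with pytest.raises(DomainError):
            pf.zscore_normalize(once)
        # re-applying the transform to already-standardized values is a no-op
        again, _ = pf.zscore_normalize(
            pf.EpochSet(data=once.data, labels=once.labels,
                        sampling_rate=once.sampling_rate))
        np.testing.assert_allclose(again.data, once.data, atol=1e-12)


def test_pipeline_preserves_labels_and_counts(small_session):
    """filter -> epoch -> downsample -> normalize keeps epoch/label alignment."""
    events = small_session.events
    es = pf.preprocess_session(small_session.signals[0],
                               small_session.sampling_rate, events,
                               epoch_samples=144, downsample_factor=2)
    assert es.n_epochs == len(events) == 72
    np.testing.assert_array_equal(es.labels,
                                  [e.is_target for e in events])
    assert es.n_time == 72 and es.sampling_rate == 120.0
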