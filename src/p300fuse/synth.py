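"""Synthetic multi-subject speller sessions.

Emulates what the collaborative-classification method assumes about real
recordings: all subjects watch the *same* flash sequence (identical event
streams), every target flash adds a subject-specific P300-like deflection —
a positive Gaussian bump (~200 ms wide) centered near 300 ms post-stimulus
with trial-to-trial latency jitter, spatially weighted toward parieto-central
electrodes — on top of 1/f (pink) background noise that is independently
generated per channel and then smoothed across neighboring channels to mimic
volume conduction.  Non-target flashes add nothing.

SNR presets scale the per-channel noise RMS relative to the subject's
template peak amplitude: ``high`` = 0.25x, ``moderate`` = 1x, ``low`` = 4x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError
from .paradigm import (DEFAULT_CHANNELS, SpellerParadigm, StimulusEvent,
                       build_event_stream)
from .preprocess import EpochSet

__all__ = ["SubjectProfile", "SynthConfig", "SyntheticSession",
           "generate_session", "grand_average", "pink_noise",
           "SNR_PRESETS", "DEFAULT_CHANNEL_WEIGHTS"]

SNR_PRESETS = {"high": 0.25, "moderate": 1.0, "low": 4.0}

#: Parieto-central spatial emphasis for Fz, Cz, P3, Pz, P4, PO7, PO8, Oz.
DEFAULT_CHANNEL_WEIGHTS = np.array(
    [0.50, 0.90, 0.70, 1.00, 0.70, 0.45, 0.45, 0.40])


@dataclass
class SubjectProfile:
    """ERP and noise parameters of one simulated subject.

    Attributes
    ----------
    p300_amplitude : float
        Peak of the target-evoked deflection in microvolts (at the
        best-weighted channel).
    p300_latency : float
        Nominal post-stimulus peak time in seconds.
    latency_jitter_sd : float
        SD in seconds of the per-trial latency jitter.
    template_width : float
        Full width of the Gaussian bump in seconds (sigma = width / 6).
    channel_weights : ndarray
        Per-channel spatial gain of the deflection.
    noise_scale : float
        Per-channel RMS in microvolts of the 1/f background.
    alpha_amplitude : float
        Optional 10 Hz sinusoid amplitude added to the background (off by
        default).
    """

    p300_amplitude: float = 8.0
    p300_latency: float = 0.300
    latency_jitter_sd: float = 0.025
    template_width: float = 0.200
    channel_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_CHANNEL_WEIGHTS.copy())
    noise_scale: float = 8.0
    alpha_amplitude: float = 0.0

    def __post_init__(self) -> None:
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if self.p300_amplitude < 0:
            raise DomainError("p300_amplitude must be >= 0")
        if self.p300_latency <= 0:
            raise DomainError("p300_latency must be > 0")
        if not np.all(np.isfinite(self.channel_weights)):
            raise DomainError("channel weights must be finite")


@dataclass
class SynthConfig:
    """Configuration of one multi-subject synthetic session.

    ``seed`` fixes *all* randomness: stimulus order, subject profiles,
    latency jitter and background noise.  ``profiles=None`` samples one
    profile per subject from realistic inter-subject ranges (amplitude
    6-12 uV, latency 280-330 ms) with the preset-determined noise scale.
    """

    paradigm: SpellerParadigm
    n_subjects: int = 2
    profiles: "Sequence[SubjectProfile] | None" = None
    snr_preset: str = "moderate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be >= 1")
        if self.snr_preset not in SNR_PRESETS:
            raise DomainError(f"snr_preset must be one of {sorted(SNR_PRESETS)}")
        if self.profiles is not None and len(self.profiles) != self.n_subjects:
            raise DomainError("need one profile per subject")


@dataclass
class SyntheticSession:
    """Per-subject continuous signals sharing one stimulus event stream."""

    signals: list                      # one (samples x channels) array each
    events: list                       # shared StimulusEvent stream
    channel_labels: list
    sampling_rate: float
    profiles: list


def pink_noise(n_samples: int, n_channels: int, rng: np.random.Generator,
               rms: float = 1.0) -> np.ndarray:
    """1/f-power noise, independent per channel, normalized to a target RMS."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.zeros(n_freq)
    scale[1:] = freqs[1:] ** -0.5          # amplitude ~ f^-1/2 => power ~ 1/f
    spectrum = (rng.standard_normal((n_freq, n_channels))
                + 1j * rng.standard_normal((n_freq, n_channels)))
    x = np.fft.irfft(spectrum * scale[:, None], n=n_samples, axis=0)
    current = x.std(axis=0, ddof=0)
    current[current == 0] = 1.0
    return x / current * rms


def _sample_profile(rng: np.random.Generator, noise_factor: float,
                    n_channels: int) -> SubjectProfile:
    amp = rng.uniform(6.0, 12.0)
    weights = (DEFAULT_CHANNEL_WEIGHTS[:n_channels] if n_channels <= 8
               else np.resize(DEFAULT_CHANNEL_WEIGHTS, n_channels))
    return SubjectProfile(
        p300_amplitude=amp,
        p300_latency=rng.uniform(0.28, 0.33),
        latency_jitter_sd=rng.uniform(0.02, 0.03),
        channel_weights=weights,
        noise_scale=noise_factor * amp)


def _smooth_channels(x: np.ndarray) -> np.ndarray:
    """Fixed [0.15, 0.7, 0.15] smoothing across the channel axis."""
    if x.shape[1] < 3:
        return x
    left = np.concatenate([x[:, :1], x[:, :-1]], axis=1)
    right = np.concatenate([x[:, 1:], x[:, -1:]], axis=1)
    return 0.15 * left + 0.70 * x + 0.15 * right


def generate_session(config: SynthConfig) -> SyntheticSession:
    """Simulate one session: shared events, per-subject continuous EEG."""
    paradigm = config.paradigm
    root = np.random.SeedSequence(config.seed)
    ss_events, ss_profiles, *ss_subjects = root.spawn(2 + config.n_subjects)

    events = build_event_stream(
        paradigm, seed=int(ss_events.generate_state(1)[0] % (2 ** 31)))
    rate = paradigm.sampling_rate
    tail = int(round(3.0 * rate))       # room for the last epoch window
    n_samples = events[-1].onset_sample + tail
    n_channels = len(DEFAULT_CHANNELS)

    noise_factor = SNR_PRESETS[config.snr_preset]
    if config.profiles is None:
        prof_rng = np.random.default_rng(ss_profiles)
        profiles = [_sample_profile(prof_rng, noise_factor, n_channels)
                    for _ in range(config.n_subjects)]
    else:
        profiles = list(config.profiles)

    target_onsets = [e.onset_sample for e in events if e.is_target]
    signals = []
    for prof, ss in zip(profiles, ss_subjects):
        rng = np.random.default_rng(ss)
        if prof.noise_scale > 0:
            sig = _smooth_channels(pink_noise(n_samples, n_channels, rng,
                                              rms=prof.noise_scale))
            # re-normalize after smoothing so the preset RMS is exact
            cur = sig.std(axis=0, ddof=0)
            cur[cur == 0] = 1.0
            sig = sig / cur * prof.noise_scale
        else:
            sig = np.zeros((n_samples, n_channels))
        if prof.alpha_amplitude > 0:
            t = np.arange(n_samples) / rate
            phases = rng.uniform(0, 2 * np.pi, n_channels)
            sig += prof.alpha_amplitude * np.sin(
                2 * np.pi * 10.0 * t[:, None] + phases[None, :])

        sigma = prof.template_width / 6.0
        # support: from onset to latency + jitter headroom + 5 sigma
        # (at 5 sigma the truncated tail is < 4e-6 of the peak)
        n_support = int(round((prof.p300_latency
                               + 5 * prof.latency_jitter_sd + 5 * sigma) * rate)) + 1
        t_from_onset = np.arange(n_support) / rate
        for onset in target_onsets:
            center = prof.p300_latency + rng.normal(0.0, prof.latency_jitter_sd)
            bump = prof.p300_amplitude * np.exp(
                -0.5 * ((t_from_onset - center) / sigma) ** 2)
            hi = min(onset + n_support, n_samples)
            sig[onset:hi] += (bump[: hi - onset, None]
                              * prof.channel_weights[None, :n_channels])
        signals.append(sig.astype(np.float32))

    return SyntheticSession(signals=signals, events=events,
                            channel_labels=list(DEFAULT_CHANNELS),
                            sampling_rate=rate, profiles=profiles)


def grand_average(epochs: EpochSet, which: str = "target") -> np.ndarray:
    """Mean waveform over one class: shape (n_time, n_channels).

    Used to verify that the target-minus-nontarget difference wave peaks
    near the configured P300 latency.
    """
    if which not in ("target", "nontarget"):
        raise DomainError("which must be 'target' or 'nontarget'")
    mask = epochs.labels if which == "target" else ~epochs.labels
    if not mask.any():
        raise DomainError(f"no {which} epochs present")
    return np.asarray(epochs.data[mask].mean(axis=0))
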