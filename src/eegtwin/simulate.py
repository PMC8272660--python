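"""Synthetic motor-imagery EEG.

Generates labelled epochs carrying the statistical structure a motor-imagery
decoder exploits: a band-limited sensorimotor rhythm whose power is attenuated
(event-related desynchronization, ERD) on a class-specific channel group, on
top of 1/f background noise, with per-subject jitter of the informative band
and optional ocular-artifact contamination.

The class effect is multiplicative on rhythm *power*: during a class-k trial
the rhythm amplitude on channel group k is scaled by sqrt(1 - erd_depth), so
the band-power ratio between a class-k trial and any other trial on those
channels approaches (1 - erd_depth) when the rhythm dominates the in-band
background.  The rhythm is band-limited filtered noise, not a sinusoid, so
spatial-filter methods see realistic trial-to-trial variability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .containers import EpochSet

#: rhythm amplitude on a designated channel, as a multiple of the in-band
#: background standard deviation.  Chosen so that the rhythm carries ~99% of
#: the in-band power and the measured class-conditional band-power ratio
#: tracks (1 - erd_depth) closely.
_RHYTHM_SNR = 10.0

#: background noise scale in nominal microvolts (standard deviation).
_BACKGROUND_UV = 10.0

#: peak amplitude of the ocular-artifact template at gain 1, in microvolts.
_ARTIFACT_UV = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the synthetic motor-imagery recordings.

    Defaults describe a 2-class, 16-channel, 250 Hz recording with a mu-band
    (8-12 Hz) rhythm, 100 trials per class, moderate ERD and +/-2 Hz
    per-subject band jitter — a realistic desk-scale motor-imagery session.
    """

    n_subjects: int = 10
    n_trials_per_class: int = 100
    n_classes: int = 2
    n_channels: int = 16
    sampling_rate: float = 250.0
    epoch_length: float = 2.0
    informative_band: Tuple[float, float] = (8.0, 12.0)
    band_jitter: float = 2.0
    erd_depth: float = 0.5
    noise_exponent: float = 1.0
    artifact_rate: float = 0.0
    artifact_gain: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.informative_band
        nyq = self.sampling_rate / 2.0
        if not (0 < low < high < nyq):
            raise ValueError(
                f"informative_band ({low}, {high}) must satisfy "
                f"0 < low < high < Nyquist ({nyq} Hz)"
            )
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if low - self.band_jitter <= 0:
            raise ValueError("band_jitter would push the band below 0 Hz")
        if high + self.band_jitter >= nyq:
            raise ValueError("band_jitter would push the band past Nyquist")
        for name in ("n_subjects", "n_trials_per_class", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def one_over_f_noise(rng: np.random.Generator, shape: Tuple[int, ...],
                n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian background with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= scale
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _band_limited_noise(rng: np.random.Generator, shape: Tuple[int, ...],
                        n_samples: int, fs: float,
                        band: Tuple[float, float]) -> np.ndarray:
    """Unit-variance stochastic oscillation confined to `band`."""
    # generate extra samples so filter transients can be discarded
    pad = n_samples // 2
    white = rng.standard_normal(shape + (n_samples + 2 * pad,))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfilt(sos, white, axis=-1)[..., pad:pad + n_samples]
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def channel_groups(n_channels: int, n_classes: int) -> np.ndarray:
    """Round-robin assignment of channels to class-designated groups.

    Channel c belongs to group ``c % n_classes``; group k is the channel set
    whose rhythm desynchronizes during class-k trials.
    """
    return np.arange(n_channels) % n_classes


def generate_subject(config: SimulationConfig, subject_index: int) -> EpochSet:
    """Generate one subject's labelled epochs.

    Trials are ordered class 0, 1, ..., repeated ``n_trials_per_class`` times
    each and then deterministically shuffled.  The subject's informative band
    is the configured band shifted by a per-subject uniform draw in
    [-band_jitter, +band_jitter].  If ``artifact_rate > 0`` an additional
    "EOG" reference channel holding the ocular waveform (plus measurement
    noise) is appended, so regression-based removal has a recorded reference.
    """
    if not 0 <= subject_index:
        raise ValueError("subject_index must be non-negative")
    ss = np.random.SeedSequence([int(config.seed), int(subject_index)])
    rng = np.random.default_rng(ss)

    n_samples = int(round(config.epoch_length * config.sampling_rate))
    n_trials = config.n_trials_per_class * config.n_classes
    fs = config.sampling_rate

    shift = rng.uniform(-config.band_jitter, config.band_jitter)
    band = (config.informative_band[0] + shift, config.informative_band[1] + shift)

    labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
    rng.shuffle(labels)

    background = _BACKGROUND_UV * one_over_f_noise(
        rng, (n_trials, config.n_channels), n_samples, fs, config.noise_exponent
    )

    # in-band background level sets the rhythm amplitude (fixed SNR)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    inband = signal.sosfiltfilt(sos, background, axis=-1)
    inband_sd = float(inband.std())
    rhythm_amp = _RHYTHM_SNR * inband_sd

    rhythm = _band_limited_noise(
        rng, (n_trials, config.n_channels), n_samples, fs, band
    )
    groups = channel_groups(config.n_channels, config.n_classes)
    # amplitude per (trial, channel): attenuated where the trial's class owns
    # the channel group
    amp = np.full((n_trials, config.n_channels), rhythm_amp)
    attenuated = labels[:, None] == groups[None, :]
    amp[attenuated] *= np.sqrt(1.0 - config.erd_depth)

    data = background + amp[:, :, None] * rhythm
    names = [f"C{i + 1}" for i in range(config.n_channels)]

    epochs = EpochSet(
        data=data,
        labels=labels,
        sampling_rate=fs,
        channel_names=names,
    )

    if config.artifact_rate > 0:
        artifact_seed = int(rng.integers(0, 2**31 - 1))
        epochs, reference = inject_eog_artifact(
            epochs, config.artifact_rate, config.artifact_gain, artifact_seed
        )
        # recorded EOG channel: artifact plus small sensor noise
        eog = reference + 0.5 * rng.standard_normal(reference.shape)
        data = np.concatenate([epochs.data, eog[:, None, :]], axis=1)
        epochs = EpochSet(
            data=data,
            labels=epochs.labels,
            sampling_rate=fs,
            channel_names=names + ["EOG"],
        )
    return epochs


def _blink_template(n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """One blink-like transient: a raised-cosine pulse (< 4 Hz content)."""
    width = int(0.5 * fs)  # 0.5 s blink
    start = int(rng.integers(0, max(1, n_samples - width)))
    t = np.arange(width)
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (width - 1)))  # 2 Hz lobe
    wave = np.zeros(n_samples)
    wave[start:start + width] = pulse
    return wave


def frontal_channels(n_channels: int) -> np.ndarray:
    """Indices of the channels designated frontal (artifact-prone)."""
    return np.arange(min(2, n_channels))


def inject_eog_artifact(
    epochs: EpochSet, rate: float, gain: float, seed: int
) -> Tuple[EpochSet, np.ndarray]:
    """Mix a low-frequency, high-amplitude ocular transient into frontal channels.

    Returns the contaminated epochs and a (n_trials, n_samples) reference
    array holding each trial's artifact waveform (zero rows for trials left
    clean), so removal quality can be scored against ground truth.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n_trials, n_channels, n_samples = epochs.data.shape
    reference = np.zeros((n_trials, n_samples))
    out = epochs.copy()
    if rate == 0.0 or gain == 0.0:
        return out, reference

    n_hit = int(round(rate * n_trials))
    hit = rng.choice(n_trials, size=n_hit, replace=False)
    front = frontal_channels(n_channels)
    # per-channel mixing weights, strongest on the most frontal channel
    weights = 1.0 / (1.0 + np.arange(len(front)))
    for t in hit:
        wave = gain * _ARTIFACT_UV * _blink_template(n_samples, epochs.sampling_rate, rng)
        reference[t] = wave
        out.data[t, front, :] += weights[:, None] * wave
    return out, reference
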