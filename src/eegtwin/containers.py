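"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass
class EpochSet:
    """Labelled multichannel EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in nominal microvolts.
    labels : ndarray of int, shape (n_trials,)
        Integer class label per trial.
    sampling_rate : float
        Samples per second; must be positive.
    channel_names : sequence of str
        One name per channel.
    band : (low, high) in Hz, optional
        Tag recording which band-pass produced this set (None = broadband).
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    channel_names: Sequence[str]
    band: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trial, channel, sample), got shape {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            labels=self.labels.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            band=self.band,
        )

    def with_data(self, data: np.ndarray, band: Optional[Tuple[float, float]] = None) -> "EpochSet":
        """Same metadata, new signal array (band tag optionally replaced)."""
        return EpochSet(
            data=data,
            labels=self.labels.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            band=self.band if band is None else band,
        )


@dataclass
class FeatureMatrix:
    """Trial-by-feature matrix with labels and feature names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trial x feature)")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("label count does not match row count")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
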