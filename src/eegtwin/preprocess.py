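"""Band-pass filter bank and adaptive artifact removal.

The filter bank splits broadband epochs into rhythm bands (theta through
gamma) ahead of spatial filtering; artifact removal regresses each data
channel on recorded reference channels (e.g. EOG) per trial — "adaptive" in
that the regression coefficients are re-estimated for every trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import EpochSet

logger = logging.getLogger(__name__)


def default_bands(low: float = 4.0, high: float = 40.0,
                  width: float = 4.0, overlap: float = 2.0) -> List[Tuple[float, float]]:
    """4-Hz-wide bands from 4-40 Hz with 2 Hz overlap (default bank)."""
    step = width - overlap
    starts = np.arange(low, high - width + 0.5 * step, step)
    return [(float(s), float(s + width)) for s in starts]


@dataclass
class FilterBankSpec:
    """Ordered set of band-pass bands plus the filter design to apply."""

    bands: List[Tuple[float, float]] = field(default_factory=default_bands)
    filter_order: int = 4
    design: str = "butter"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank needs at least one band")
        for low, high in self.bands:
            if not 0 < low < high:
                raise ValueError(f"invalid band ({low}, {high})")
        if self.design != "butter":
            raise ValueError(f"unsupported filter design {self.design!r}")


def bandpass(epochs: EpochSet, band: Tuple[float, float], order: int = 4) -> EpochSet:
    """Zero-phase band-pass of every trial and channel.

    Forward-backward IIR (Butterworth) filtering, so the pass band keeps its
    phase structure — essential for covariance-based spatial filters.
    """
    low, high = band
    if not 0 < low < high < epochs.nyquist:
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={epochs.nyquist}) Hz"
        )
    sos = signal.butter(order, (low, high), btype="bandpass",
                        fs=epochs.sampling_rate, output="sos")
    # sosfiltfilt pads by reflection; require enough samples for the warm-up
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if epochs.n_samples <= padlen:
        raise ValueError(
            f"epoch of {epochs.n_samples} samples shorter than the filter "
            f"warm-up ({padlen} samples); use longer epochs or a lower order"
        )
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(filtered, band=(low, high))


def apply_filter_bank(epochs: EpochSet, spec: FilterBankSpec) -> List[EpochSet]:
    """One band-tagged EpochSet per band; labels and trial order preserved."""
    logger.info("filter bank: %s", spec.bands)
    return [bandpass(epochs, band, spec.filter_order) for band in spec.bands]


def remove_artifacts(epochs: EpochSet, reference_channels: Sequence[str]) -> EpochSet:
    """Per-trial least-squares regression of data channels on reference channels.

    For each trial, every non-reference channel x is replaced by
    ``x - R beta`` with ``beta`` the least-squares solution of ``R beta = x``
    over the trial's samples (R = reference channels).  Coefficients are
    re-estimated per trial, which is what makes the removal adaptive.
    Reference channels are dropped from the output.  A reference channel that
    is identically zero in a trial contributes coefficient 0 (and is logged).
    """
    names = list(epochs.channel_names)
    missing = [c for c in reference_channels if c not in names]
    if missing:
        raise ValueError(f"reference channels not in epoch set: {missing}")
    if not reference_channels:
        return epochs.copy()
    ref_idx = np.array([names.index(c) for c in reference_channels])
    keep_idx = np.array([i for i in range(len(names)) if i not in set(ref_idx)])

    cleaned = np.empty((epochs.n_trials, len(keep_idx), epochs.n_samples))
    for t in range(epochs.n_trials):
        refs = epochs.data[t, ref_idx, :]        # (n_ref, n_samples)
        live = np.ptp(refs, axis=1) > 0
        if not np.all(live):
            logger.warning(
                "trial %d: constant reference channel(s) skipped (coefficient 0)", t
            )
        x = epochs.data[t, keep_idx, :]
        if np.any(live):
            R = refs[live].T                     # (n_samples, n_live)
            beta, *_ = np.linalg.lstsq(R, x.T, rcond=None)
            cleaned[t] = x - (R @ beta).T
        else:
            cleaned[t] = x
    return EpochSet(
        data=cleaned,
        labels=epochs.labels.copy(),
        sampling_rate=epochs.sampling_rate,
        channel_names=[names[i] for i in keep_idx],
        band=epochs.band,
    )
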