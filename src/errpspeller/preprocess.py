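"""Continuous recording -> analysis-ready ErrP epochs.

The chain mirrors standard single-trial ERP practice: zero-phase Butterworth
band-pass on the continuous signal (1-10 Hz for interaction ErrPs), epoch
extraction time-locked to each command delivery, decimation to 64 Hz, and
restriction to the fronto-central decoding channels. Filtering happens on
the continuous data *before* cutting so that filter edge transients never
touch epoch boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .events import EventLog
from .synth import ContinuousRecording

__all__ = ["EpochSet", "bandpass_filter", "extract_epochs", "downsample",
           "select_channels"]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Epochs x channels x time tensor with per-epoch metadata.

    ``window`` is (start, end) in seconds relative to the command-delivery
    event; ``shifts`` holds the per-epoch realignment correction in seconds
    (zero until realignment; positive means the epoch content was moved
    later in time).
    """

    data: np.ndarray
    rate: float
    window: tuple[float, float]
    is_error: np.ndarray
    word_ids: np.ndarray
    shifts: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.is_error = np.asarray(self.is_error, dtype=bool)
        self.word_ids = np.asarray(self.word_ids, dtype=int)
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, time)")
        n_ep, n_ch, n_t = self.data.shape
        if not (len(self.is_error) == len(self.word_ids) == len(self.shifts) == n_ep):
            raise ValueError("per-epoch metadata length mismatch")
        if len(self.channels) != n_ch:
            raise ValueError("channel names do not match data")
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed start")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain NaN or Inf")
        expected = (self.window[1] - self.window[0]) * self.rate
        if abs(n_t - expected) > 1.0 + 1e-6:
            raise ValueError(
                f"time axis ({n_t} samples) inconsistent with window/rate "
                f"(expected ~{expected:.1f})"
            )

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to the event."""
        return self.window[0] + np.arange(self.n_times) / self.rate

    @property
    def labels(self) -> np.ndarray:
        """String labels, ``"error"`` / ``"correct"`` per epoch."""
        return np.where(self.is_error, "error", "correct")

    def select_epochs(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], is_error=self.is_error[mask],
                       word_ids=self.word_ids[mask], shifts=self.shifts[mask])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def bandpass_filter(rec: ContinuousRecording, low: float = 1.0,
                    high: float = 10.0, order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    The filter of the stated design ``order`` is applied forward and backward
    (``sosfiltfilt``), preserving peak latencies at the cost of doubling the
    effective attenuation; output length equals input length.
    """
    nyq = rec.rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq:g} Hz); "
            f"got ({low:g}, {high:g})"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(data=filtered, rate=rec.rate, layout=rec.layout,
                               start_time=rec.start_time)


def extract_epochs(rec: ContinuousRecording, events: EventLog,
                   window: tuple[float, float] = (0.0, 1.0),
                   baseline: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Cut one epoch per command-delivery event, time-locked at t=0.

    Events whose window falls (even partly) outside the recording are
    dropped, with the count logged. When the epoch window contains the
    ``baseline`` interval, the per-channel baseline mean is subtracted
    (common ERP practice); the default feature window [0, 1] s has no
    baseline segment and is left untouched.
    """
    w0, w1 = window
    n_t = int(round((w1 - w0) * rec.rate))
    if n_t <= 0:
        raise ValueError("window must span at least one sample")
    starts = np.round((events.time_s - rec.start_time + w0) * rec.rate).astype(int)
    keep = (starts >= 0) & (starts + n_t <= rec.n_samples)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("extract_epochs: dropped %d events at recording edges",
                    n_dropped)
    if not np.any(keep):
        raise ValueError("no epoch fits inside the recording")

    kept = events.subset(keep)
    data = np.stack([rec.data[:, s:s + n_t] for s in starts[keep]])

    if baseline is not None and w0 <= baseline[0] and w1 >= baseline[1]:
        b0 = int(round((baseline[0] - w0) * rec.rate))
        b1 = int(round((baseline[1] - w0) * rec.rate))
        if b1 > b0:
            data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)

    return EpochSet(
        data=data, rate=rec.rate, window=(w0, w1), is_error=kept.is_error,
        word_ids=kept.word_id, shifts=np.zeros(len(kept)),
        channels=rec.layout.names,
    )


def downsample(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Decimate epochs to ``target_rate`` Hz.

    The preceding 1-10 Hz band-pass acts as the anti-alias filter, so an
    integer-factor decimation is a plain stride; non-integer ratios go
    through polyphase resampling. Labels, word ids and shifts are preserved.
    """
    if target_rate > epochs.rate:
        raise ValueError(
            f"target rate {target_rate:g} Hz exceeds epoch rate {epochs.rate:g} Hz"
        )
    if target_rate == epochs.rate:
        return replace(epochs, data=epochs.data.copy())
    ratio = epochs.rate / target_rate
    n_out = int(epochs.n_times * target_rate / epochs.rate)
    if abs(ratio - round(ratio)) < 1e-9:
        data = epochs.data[:, :, :: int(round(ratio))][:, :, :n_out]
    else:
        frac = Fraction(target_rate / epochs.rate).limit_denominator(1000)
        data = signal.resample_poly(epochs.data, frac.numerator,
                                    frac.denominator, axis=2)[:, :, :n_out]
    return replace(epochs, data=data, rate=target_rate)


def select_channels(epochs: EpochSet, subset) -> EpochSet:
    """Restrict epochs to ``subset`` channel names, in the requested order."""
    idx = [epochs.channel_index(name) for name in subset]
    return replace(epochs, data=epochs.data[:, idx, :], channels=tuple(subset))
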