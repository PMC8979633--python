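"""Synthetic EEG session generator.

Emulates the statistical structure of a motor-imagery (MI) speller session
recorded over fronto-central cortex:

* an interaction error-related potential (ErrP) — an early negativity near
  250 ms followed by a positivity near 500 ms after an erroneous command —
  inserted at every error event with single-trial latency jitter and
  amplitude variability, spatially weighted toward the fronto-central /
  centro-parietal midline;
* flat (no added deflection) activity after correct commands;
* sensorimotor-rhythm (mu / beta) oscillations over the motor strip whose
  power desynchronises (ERD) during MI periods, lateralised by imagined
  hand;
* 1/f ("pink") background noise, optionally with 50 Hz line interference.

All randomness flows through a single :func:`numpy.random.default_rng` seed:
identical inputs give bit-identical recordings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .events import EventLog
from .layout import ChannelLayout, default_layout

__all__ = [
    "ErrPTemplateParams",
    "SMRParams",
    "NoiseParams",
    "ContinuousRecording",
    "make_errp_waveform",
    "generate_session",
    "default_spatial_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrPTemplateParams:
    """Shape and variability of the inserted interaction-ErrP template.

    The template is a sum of two Gaussian-windowed bumps: a negativity at
    ``neg_latency`` and a positivity at ``pos_latency`` (seconds after the
    command), each truncated to zero beyond three widths from its centre.
    ``jitter_sd`` jitters the single-trial onset latency; ``amplitude_cv``
    scales each insertion by a positive truncated-normal gain.
    """

    neg_latency: float = 0.250      # s
    neg_amplitude: float = -8.0     # microvolt
    neg_width: float = 0.032        # s (Gaussian sd)
    pos_latency: float = 0.500      # s
    pos_amplitude: float = 9.0      # microvolt
    pos_width: float = 0.040        # s (Gaussian sd)
    spatial_weights: np.ndarray | None = None
    jitter_sd: float = 0.030        # s
    amplitude_cv: float = 0.25      # unitless

    def __post_init__(self) -> None:
        if not 0.0 < self.neg_latency < self.pos_latency:
            raise ValueError("require 0 < neg_latency < pos_latency")
        if self.neg_width <= 0 or self.pos_width <= 0:
            raise ValueError("peak widths must be positive")
        if self.jitter_sd < 0 or self.amplitude_cv < 0:
            raise ValueError("jitter_sd and amplitude_cv must be >= 0")
        if self.spatial_weights is not None:
            w = np.asarray(self.spatial_weights, dtype=float)
            if not np.all(np.isfinite(w)):
                raise ValueError("spatial_weights must be finite")
            object.__setattr__(self, "spatial_weights", w)

    @property
    def support(self) -> float:
        """Template duration: latest point of non-zero amplitude (s)."""
        return self.pos_latency + 3.0 * self.pos_width


@dataclass(frozen=True)
class SMRParams:
    """Sensorimotor-rhythm model: band-limited mu/beta oscillations whose
    power drops by ``erd_depth`` over the contralateral motor channels
    during an MI period (event-related desynchronisation). ``lateralization``
    in [0, 1] sets how much weaker the ipsilateral ERD is (1 = purely
    contralateral)."""

    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    erd_depth: float = 0.5
    lateralization: float = 0.5
    mu_amplitude: float = 6.0    # microvolt rms at rest
    beta_amplitude: float = 3.0  # microvolt rms at rest

    def __post_init__(self) -> None:
        for lo, hi in (self.mu_band, self.beta_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must be ordered and positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Background noise: 1/f^exponent spectrum scaled to ``noise_sd``
    microvolts rms per channel, plus optional 50 Hz line interference."""

    pink_exponent: float = 1.0
    noise_sd: float = 20.0       # microvolt
    line_noise_amp: float = 0.0  # microvolt at 50 Hz

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ContinuousRecording:
    """A multichannel EEG recording: ``data`` is channels x samples in
    microvolts at ``rate`` Hz, rows ordered as ``layout.names``."""

    data: np.ndarray
    rate: float
    layout: ChannelLayout
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.layout):
            raise ValueError(
                f"data must be ({len(self.layout)}, n_samples), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.index(name)]


def default_spatial_weights(layout: ChannelLayout, sigma: float = 0.30) -> np.ndarray:
    """Unit-peak Gaussian fall-off from the FCz-CPz midline axis.

    Each channel's weight is ``exp(-d^2 / (2 sigma^2))`` where ``d`` is its
    distance to the nearest point of the segment joining FCz and CPz (or to
    the vertex if those labels are absent from the layout).
    """
    pos = layout.positions
    try:
        a = pos[layout.index("FCz")]
        b = pos[layout.index("CPz")]
    except KeyError:
        a = b = np.zeros(2)
    ab = b - a
    denom = float(ab @ ab) or 1.0
    t = np.clip(((pos - a) @ ab) / denom, 0.0, 1.0)
    nearest = a + t[:, None] * ab
    d = np.linalg.norm(pos - nearest, axis=1)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def make_errp_waveform(
    params: ErrPTemplateParams, rate: float, duration: float
) -> np.ndarray:
    """Single-channel ErrP template sampled at ``rate`` over ``duration``.

    Sum of a negative Gaussian bump at ``neg_latency`` and a positive one at
    ``pos_latency``; each bump is exactly zero beyond three widths from its
    centre so that epochs outside the template support stay flat.
    """
    min_dur = params.support
    if duration <= min_dur:
        raise ValueError(
            f"duration {duration:g} s too short; need > pos_latency + "
            f"3*pos_width = {min_dur:g} s"
        )
    t = np.arange(int(round(duration * rate))) / rate
    wave = np.zeros_like(t)
    for lat, amp, width in (
        (params.neg_latency, params.neg_amplitude, params.neg_width),
        (params.pos_latency, params.pos_amplitude, params.pos_width),
    ):
        bump = amp * np.exp(-((t - lat) ** 2) / (2.0 * width ** 2))
        bump[np.abs(t - lat) > 3.0 * width] = 0.0
        wave += bump
    return wave


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float
                ) -> np.ndarray:
    """Unit-rms noise with a 1/f^exponent power spectrum per row."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.rfft(rng.standard_normal(shape), axis=-1) * scale
    x = np.fft.irfft(shaped, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                      rate: float) -> np.ndarray:
    """Unit-rms band-limited Gaussian noise (4th-order Butterworth band)."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std() or 1.0
    return x / sd


# Motor-strip channel groups carrying lateralised SMR activity.
_LEFT_MOTOR = ("C3", "C1", "FC3", "CP1")
_RIGHT_MOTOR = ("C4", "C2", "FC4", "CP2")


def _truncated_gain(rng: np.random.Generator, cv: float) -> float:
    """Normal(1, cv) resampled until positive (polarity never flips)."""
    if cv == 0:
        return 1.0
    for _ in range(100):
        g = rng.normal(1.0, cv)
        if g > 0:
            return float(g)
    return 1e-3


def generate_session(
    layout: ChannelLayout | None,
    errp: ErrPTemplateParams,
    smr: SMRParams,
    noise: NoiseParams,
    event_plan: EventLog,
    seed: int,
    rate: float = 512.0,
    duration: float | None = None,
    feedback_interference: float = 0.0,
) -> tuple[ContinuousRecording, EventLog]:
    """Render a continuous recording realising ``event_plan``.

    For every event flagged as an error, a jittered, amplitude-scaled copy of
    the ErrP template (times the per-channel spatial weights) is added at the
    event time. Correct events add nothing. Each event's MI period
    ``[time - duration_s, time]`` carries ERD of the SMR oscillations
    according to the intended MI class. Background is 1/f noise.

    ``feedback_interference`` (default 0) attenuates ErrP amplitude by
    ``1 - f`` and inflates latency jitter by ``1 + f`` for events in the
    FBon condition, to exercise the condition-comparison machinery under the
    alternative hypothesis; the default null matches the finding that
    feedback does not alter the ErrP.

    Returns the recording and an unchanged copy of the event log.
    """
    if layout is None:
        layout = default_layout()
    n_events = len(event_plan)
    support = errp.support
    if duration is None:
        duration = (event_plan.time_s[-1] + 2.0) if n_events else 10.0
    if n_events and event_plan.time_s[-1] + support > duration:
        raise ValueError("event plan extends beyond the recording duration")
    if n_events and event_plan.time_s[0] < 0:
        raise ValueError("event times must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    n_ch = len(layout)

    data = _pink_noise(rng, (n_ch, n), noise.pink_exponent) * noise.noise_sd
    if noise.noise_sd == 0:
        data[:] = 0.0
    t_axis = np.arange(n) / rate
    if noise.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += noise.line_noise_amp * np.sin(2 * np.pi * 50.0 * t_axis + phase)

    # --- sensorimotor rhythms with MI-locked ERD ------------------------
    left_idx = [layout.index(c) for c in _LEFT_MOTOR if c in layout.names]
    right_idx = [layout.index(c) for c in _RIGHT_MOTOR if c in layout.names]
    if left_idx or right_idx:
        # power envelopes per hemisphere, 1 at rest
        env_left = np.ones(n)
        env_right = np.ones(n)
        ipsi_depth = smr.erd_depth * (1.0 - smr.lateralization)
        for i in range(n_events):
            t1 = event_plan.time_s[i]
            t0 = max(0.0, t1 - event_plan.duration_s[i])
            s0, s1 = int(round(t0 * rate)), min(int(round(t1 * rate)), n)
            if s1 <= s0:
                continue
            if event_plan.intended[i] == "right":  # right hand -> left hemi ERD
                env_left[s0:s1] = 1.0 - smr.erd_depth
                env_right[s0:s1] = 1.0 - ipsi_depth
            else:
                env_right[s0:s1] = 1.0 - smr.erd_depth
                env_left[s0:s1] = 1.0 - ipsi_depth
        amp_left = np.sqrt(env_left)
        amp_right = np.sqrt(env_right)
        for band, amp in ((smr.mu_band, smr.mu_amplitude),
                          (smr.beta_band, smr.beta_amplitude)):
            if amp <= 0:
                continue
            for idx_set, envelope in ((left_idx, amp_left), (right_idx, amp_right)):
                for ch in idx_set:
                    osc = _narrowband_noise(rng, n, band, rate)
                    data[ch] += amp * envelope * osc

    # --- ErrP insertions ------------------------------------------------
    weights = (errp.spatial_weights if errp.spatial_weights is not None
               else default_spatial_weights(layout))
    if len(weights) != n_ch:
        raise ValueError("spatial_weights length does not match layout")
    template = make_errp_waveform(errp, rate, support + 2.0 / rate)
    err_times = event_plan.time_s[event_plan.is_error]
    if len(err_times) > 1 and np.any(np.diff(err_times) < support):
        warnings.warn(
            "ErrP insertions closer than the template support; overlapping "
            "responses are added together", stacklevel=2)
    for i in range(n_events):
        if event_plan.correct[i]:
            continue
        jitter_sd = errp.jitter_sd
        gain_scale = 1.0
        if feedback_interference > 0 and event_plan.condition[i] == "FBon":
            jitter_sd *= 1.0 + feedback_interference
            gain_scale = 1.0 - feedback_interference
        onset = event_plan.time_s[i] + rng.normal(0.0, jitter_sd) if jitter_sd else \
            event_plan.time_s[i]
        gain = gain_scale * _truncated_gain(rng, errp.amplitude_cv)
        s0 = int(round(onset * rate))
        seg = template
        if s0 < 0:
            seg = seg[-s0:]
            s0 = 0
        s1 = min(s0 + len(seg), n)
        data[:, s0:s1] += gain * np.outer(weights, seg[: s1 - s0])

    rec = ContinuousRecording(data=data, rate=rate, layout=layout)
    events = EventLog.from_frame(event_plan.to_frame())
    logger.debug("generated session: %d channels, %.1f s, %d events (%d errors)",
                 n_ch, duration, n_events, events.n_errors)
    return rec, events
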