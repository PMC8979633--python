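"""End-to-end convenience drivers.

Glue over the library modules: simulate one subject's session (speller
protocol + synthetic EEG), run the preprocessing chain, and evaluate the
ErrP detector with word-wise cross-validation — the three steps every
analysis script repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CVResult, crossvalidate_by_word
from .events import EventLog
from .layout import DECODING_CHANNELS_8, ChannelLayout, default_layout
from .preprocess import (EpochSet, bandpass_filter, downsample, extract_epochs,
                         select_channels)
from .speller import DEFAULT_ERROR_PROB, DEFAULT_WORDS, plan_session, run_session
from .synth import (ContinuousRecording, ErrPTemplateParams, NoiseParams,
                    SMRParams, generate_session)

__all__ = ["simulate_subject", "preprocess_session", "analyze_session",
           "SimulatedSubject"]


@dataclass
class SimulatedSubject:
    recording: ContinuousRecording
    events: EventLog
    condition: str
    seed: int


def simulate_subject(
    seed: int,
    condition: str = "FBoff",
    words=DEFAULT_WORDS,
    error_prob: float = DEFAULT_ERROR_PROB,
    layout: ChannelLayout | None = None,
    errp: ErrPTemplateParams | None = None,
    smr: SMRParams | None = None,
    noise: NoiseParams | None = None,
    rate: float = 512.0,
    feedback_interference: float = 0.0,
) -> SimulatedSubject:
    """Simulate one subject x condition session under default study
    conditions: 6 words, 20% command error rate, default ErrP morphology."""
    layout = layout or default_layout()
    plan = plan_session(words, condition, seed)
    events = run_session(plan, error_prob)
    rec, events = generate_session(
        layout, errp or ErrPTemplateParams(), smr or SMRParams(),
        noise or NoiseParams(), events, seed=seed, rate=rate,
        feedback_interference=feedback_interference,
    )
    return SimulatedSubject(recording=rec, events=events,
                            condition=condition, seed=seed)


def preprocess_session(
    rec: ContinuousRecording,
    events: EventLog,
    low: float = 1.0,
    high: float = 10.0,
    order: int = 4,
    window: tuple[float, float] = (0.0, 1.0),
    target_rate: float = 64.0,
    channels=DECODING_CHANNELS_8,
) -> EpochSet:
    """Standard ErrP chain: 1-10 Hz zero-phase band-pass on the continuous
    data, epoch at each command, decimate to 64 Hz, keep the fronto-central
    decoding channels (pass ``channels=None`` to keep all)."""
    filtered = bandpass_filter(rec, low=low, high=high, order=order)
    epochs = extract_epochs(filtered, events, window=window)
    epochs = downsample(epochs, target_rate)
    if channels is not None:
        epochs = select_channels(epochs, channels)
    return epochs


def analyze_session(rec: ContinuousRecording, events: EventLog,
                    k_features: int = 60, realign: bool = True,
                    **preprocess_kwargs) -> CVResult:
    """Preprocess and cross-validate one session; returns the CV result."""
    epochs = preprocess_session(rec, events, **preprocess_kwargs)
    return crossvalidate_by_word(epochs, k_features=k_features, realign=realign)
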