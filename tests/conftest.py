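"""Shared fixtures: small, quickly generated synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

import errpspeller as e


@pytest.fixture(scope="session")
def layout():
    return e.default_layout()


@pytest.fixture(scope="session")
def small_subject():
    """A short but complete FBoff session (two 2-letter words) used by many
    structural tests; ~30 commands, a handful of errors."""
    return e.simulate_subject(seed=7, words=("ace", "bed"))


@pytest.fixture(scope="session")
def small_epochs(small_subject):
    return e.preprocess_session(small_subject.recording, small_subject.events)


def make_template_epochs(template: np.ndarray, shifts_samples, rate: float = 64.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         n_correct: int = 0,
                         channels=("FCz", "CPz")) -> "e.EpochSet":
    """Build an EpochSet whose error epochs are integer-shifted copies of a
    (channels x time) template — ground truth for realignment tests."""
    rng = np.random.default_rng(seed)
    n_ch, n_t = template.shape
    eps = []
    for s in shifts_samples:
        ep = np.empty_like(template)
        if s >= 0:
            ep[:, s:] = template[:, : n_t - s]
            ep[:, :s] = template[:, :1]
        else:
            ep[:, :s] = template[:, -s:]
            ep[:, s:] = template[:, -1:]
        eps.append(ep + noise_sd * rng.standard_normal(template.shape))
    for _ in range(n_correct):
        eps.append(noise_sd * rng.standard_normal(template.shape))
    data = np.stack(eps)
    n = len(eps)
    is_error = np.array([True] * len(shifts_samples) + [False] * n_correct)
    return e.EpochSet(
        data=data, rate=rate, window=(0.0, n_t / rate), is_error=is_error,
        word_ids=np.arange(n) % 2, shifts=np.zeros(n),
        channels=tuple(channels[:n_ch]),
    )
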