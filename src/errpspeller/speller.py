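"""Pseudo-online speller protocol.

Emulates a two-class MI speller session under playback control: the cursor
moves left/right along a linear alphabet toward the target character
(dwelling on it selects), each command is produced by "playing back" a
surrogate MI trial, and the delivered direction is wrong with a fixed
probability (20% by default — the controlled error rate that elicits
ErrPs). Erroneous commands are automatically reverted a fixed delay later,
so the session always terminates; the error stays in the log for ErrP
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import CONDITIONS, EventLog
from .midecoder import DecoderConfig, EvidenceState, accumulate_evidence

__all__ = [
    "ALPHABET", "DEFAULT_WORDS", "DEFAULT_ERROR_PROB",
    "TrialDurationParams", "SessionPlan", "TrialOutcome", "SpellerState",
    "plan_session", "playback_trial", "run_session", "min_commands",
]

#: Linear character array of the abstracted cursor model.
ALPHABET = "abcdefghijklmnopqrstuvwxyz_"

#: Cursor home position (array centre); selection resets the cursor here.
HOME = len(ALPHABET) // 2

#: Default six target words per condition (the protocol spells 6 words).
#: Letters far from the alphabet centre give long cursor paths, hence many
#: commands (~430) and a solid count of error epochs (~85) per session.
DEFAULT_WORDS: tuple[str, ...] = ("because", "crazy", "wizard", "vacuum",
                                  "zebra", "cabbage")

#: Fixed command error probability of the playback controller.
DEFAULT_ERROR_PROB = 0.2

#: Pause between a delivered command and the next MI trial onset (s).
INTER_TRIAL_GAP = 1.0

#: Delay after an erroneous command at which the automatic correction
#: reverts the speller state (s).
CORRECTION_DELAY = 1.0


@dataclass(frozen=True)
class TrialDurationParams:
    """Log-normal surrogate MI trial durations, median ``median_s`` seconds,
    clipped to [``min_s``, ``max_s``] (a parametric stand-in for a playback
    database of recorded trials)."""

    median_s: float = 3.0
    sigma: float = 0.35
    min_s: float = 1.5
    max_s: float = 7.0

    def draw(self, rng: np.random.Generator) -> float:
        d = float(np.exp(np.log(self.median_s) + self.sigma * rng.standard_normal()))
        return float(np.clip(d, self.min_s, self.max_s))


@dataclass(frozen=True)
class SessionPlan:
    """Words to spell in one condition, with the trial-duration model."""

    words: tuple[str, ...]
    condition: str
    trial_params: TrialDurationParams
    seed: int


@dataclass
class TrialOutcome:
    """One played-back MI trial: the delivered command, its correctness, its
    duration, and the evidence-accumulation trace that produced it."""

    duration: float
    delivered: str
    intended: str
    correct: bool
    evidence_trace: np.ndarray

    def __post_init__(self) -> None:
        if self.correct != (self.delivered == self.intended):
            raise ValueError("correct flag inconsistent")


@dataclass
class SpellerState:
    """Abstracted cursor state while spelling ``target_word``."""

    target_word: str
    typed_prefix: str = ""
    cursor_position: int = HOME
    pending_correction: bool = False

    def __post_init__(self) -> None:
        if not self.target_word.startswith(self.typed_prefix) and \
                self.typed_prefix != self.target_word:
            raise ValueError("typed_prefix must be a prefix of target_word")
        if not 0 <= self.cursor_position < len(ALPHABET):
            raise ValueError("cursor_position out of bounds")

    @property
    def done(self) -> bool:
        return self.typed_prefix == self.target_word

    @property
    def target_char_index(self) -> int:
        return ALPHABET.index(self.target_word[len(self.typed_prefix)])

    def intended_direction(self) -> str:
        """Re-planned after every command: toward the next target character."""
        return "left" if self.target_char_index < self.cursor_position else "right"


def _check_word(word: str) -> None:
    for c in word:
        if c not in ALPHABET:
            raise ValueError(f"character {c!r} outside the speller alphabet")


def min_commands(word: str) -> int:
    """Minimal number of cursor commands to spell ``word`` without errors:
    the cursor walks from home to each character (dwell selects, then the
    cursor returns home)."""
    _check_word(word)
    return sum(abs(ALPHABET.index(c) - HOME) for c in word)


def plan_session(words, condition: str, seed: int,
                 trial_params: TrialDurationParams | None = None) -> SessionPlan:
    """Validate and freeze a session plan (deterministic given ``seed``)."""
    words = tuple(words)
    if not words:
        raise ValueError("word list must be non-empty")
    for w in words:
        _check_word(w)
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    return SessionPlan(words=words, condition=condition,
                       trial_params=trial_params or TrialDurationParams(),
                       seed=int(seed))


def playback_trial(intended: str, error_prob: float = DEFAULT_ERROR_PROB,
                   trial_params: TrialDurationParams | None = None,
                   seed: int | np.random.Generator = 0,
                   decoder_cfg: DecoderConfig | None = None) -> TrialOutcome:
    """Play back one surrogate MI trial.

    The delivered direction equals ``intended`` with probability
    ``1 - error_prob``; the duration is drawn from ``trial_params``; the
    evidence trace feeds posteriors biased toward the *delivered* class
    through :func:`errpspeller.midecoder.accumulate_evidence` until the
    decision threshold is crossed on that side.
    """
    if not 0.0 <= error_prob <= 1.0:
        raise ValueError("error_prob must be in [0, 1]")
    trial_params = trial_params or TrialDurationParams()
    cfg = decoder_cfg or DecoderConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    is_error = bool(rng.random() < error_prob)
    delivered = intended if not is_error else \
        ("left" if intended == "right" else "right")
    duration = trial_params.draw(rng)

    target_q = 0.85 if delivered == "right" else 0.15
    state = EvidenceState()
    decision = None
    for step in range(4000):
        if step < 2000:
            q = float(np.clip(rng.normal(target_q, 0.10), 0.0, 1.0))
        else:  # failsafe: drive deterministically toward the delivered side
            q = 0.99 if delivered == "right" else 0.01
        state, decision = accumulate_evidence(state, q, cfg)
        if decision == delivered:
            break
        if decision is not None:  # crossed the wrong side; keep accumulating
            decision = None
    trace = np.asarray(state.history)
    return TrialOutcome(duration=duration, delivered=delivered,
                        intended=intended, correct=not is_error,
                        evidence_trace=trace)


def run_session(plan: SessionPlan, error_prob: float = DEFAULT_ERROR_PROB,
                seed: int | None = None, max_commands: int = 20000) -> EventLog:
    """Spell every word of ``plan`` through the playback controller.

    After each erroneous command the cursor is reverted ``CORRECTION_DELAY``
    seconds later (automatic error-correction); the erroneous event remains
    in the log. Events carry the word id and condition for fold assignment.
    Raises if ``max_commands`` is exhausted before the session terminates.
    """
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    times, intended_l, delivered_l, correct_l, word_l, dur_l = \
        [], [], [], [], [], []
    t = 0.0
    n_cmd = 0
    for word_id, word in enumerate(plan.words):
        state = SpellerState(target_word=word)
        while not state.done:
            if state.target_char_index == state.cursor_position:
                # dwell selects without a command; cursor returns home
                state.typed_prefix += word[len(state.typed_prefix)]
                state.cursor_position = HOME
                continue
            n_cmd += 1
            if n_cmd > max_commands:
                raise RuntimeError(
                    f"session did not terminate within {max_commands} commands"
                )
            intended = state.intended_direction()
            outcome = playback_trial(intended, error_prob, plan.trial_params,
                                     seed=rng)
            t += INTER_TRIAL_GAP + outcome.duration
            times.append(t)
            intended_l.append(intended)
            delivered_l.append(outcome.delivered)
            correct_l.append(outcome.correct)
            word_l.append(word_id)
            dur_l.append(outcome.duration)
            step = -1 if outcome.delivered == "left" else 1
            new_pos = int(np.clip(state.cursor_position + step, 0,
                                  len(ALPHABET) - 1))
            if outcome.correct:
                state.cursor_position = new_pos
            else:
                # cursor moves, then the automatic correction reverts it
                t += CORRECTION_DELAY
    return EventLog(
        time_s=times, intended=intended_l, delivered=delivered_l,
        correct=correct_l, word_id=word_l,
        condition=[plan.condition] * len(times), duration_s=dur_l,
    )
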