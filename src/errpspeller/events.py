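"""Command-delivery event logs.

Every speller command delivered during a session becomes one event: the time
the command landed, the direction the user intended, the direction the
controller actually delivered, the correctness flag, the id of the word being
spelled (the later cross-validation fold), the experimental condition
(``FBon`` / ``FBoff``) and the duration of the motor-imagery trial that
produced the command.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = ["EventLog", "CONDITIONS", "DIRECTIONS", "EVENT_COLUMNS"]

CONDITIONS = ("FBon", "FBoff")
DIRECTIONS = ("left", "right")

EVENT_COLUMNS = (
    "time_s", "intended", "delivered", "correct",
    "word_id", "condition", "duration_s",
)


@dataclass
class EventLog:
    """Ordered command-delivery events of one spelling session.

    Attributes
    ----------
    time_s
        Command delivery times in seconds, strictly increasing.
    intended, delivered
        Intended / delivered cursor direction, ``"left"`` or ``"right"``.
    correct
        ``delivered == intended`` per event (stored, and validated).
    word_id
        Index of the word being spelled; defines blocked CV folds.
    condition
        ``"FBon"`` or ``"FBoff"`` per event.
    duration_s
        Duration of the motor-imagery trial preceding each command; the MI
        period of event *i* is ``[time_s[i] - duration_s[i], time_s[i]]``.
    """

    time_s: np.ndarray
    intended: np.ndarray
    delivered: np.ndarray
    correct: np.ndarray
    word_id: np.ndarray
    condition: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intended = np.asarray(self.intended, dtype="U8")
        self.delivered = np.asarray(self.delivered, dtype="U8")
        self.correct = np.asarray(self.correct, dtype=bool)
        self.word_id = np.asarray(self.word_id, dtype=int)
        self.condition = np.asarray(self.condition, dtype="U8")
        self.duration_s = np.asarray(self.duration_s, dtype=float)

        n = len(self.time_s)
        for f in fields(self):
            if len(getattr(self, f.name)) != n:
                raise ValueError(f"field {f.name!r} has wrong length")
        if n and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("event times must be strictly increasing")
        if not np.array_equal(self.correct, self.intended == self.delivered):
            raise ValueError("correct flags inconsistent with intended/delivered")
        bad = set(self.intended) | set(self.delivered)
        if n and not bad <= set(DIRECTIONS):
            raise ValueError(f"directions must be in {DIRECTIONS}, got {sorted(bad)}")
        if n and not set(self.condition) <= set(CONDITIONS):
            raise ValueError(f"condition labels must be in {CONDITIONS}")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def is_error(self) -> np.ndarray:
        return ~self.correct

    @property
    def n_errors(self) -> int:
        return int(np.sum(~self.correct))

    @classmethod
    def empty(cls) -> "EventLog":
        z: list = []
        return cls(z, z, z, z, z, z, z)

    def subset(self, mask) -> "EventLog":
        mask = np.asarray(mask)
        return EventLog(*(getattr(self, f.name)[mask] for f in fields(self)))

    # ---- tabular round trips -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in EVENT_COLUMNS})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventLog":
        missing = set(EVENT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        return cls(*(frame[c].to_numpy() for c in EVENT_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f.name), getattr(other, f.name))
            for f in fields(self)
        )
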