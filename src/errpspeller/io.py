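"""Recording container I/O.

One file per subject x condition, in NumPy ``.npz`` (compressed-array) form,
holding the channels x samples signal (float64 microvolts), sampling rate,
channel names and unit-disc positions, start time, and the full event table.
A ``format_version`` tag guards against silently reading foreign files.
Round trips are bit-exact for every field.
"""

from __future__ import annotations

import numpy as np

from .events import EVENT_COLUMNS, EventLog
from .layout import ChannelLayout
from .synth import ContinuousRecording

__all__ = ["write_recording", "read_recording", "RecordingFormatError",
           "FORMAT_VERSION"]

FORMAT_VERSION = "errpspeller.recording/1"


class RecordingFormatError(ValueError):
    """Raised when a container file is malformed or of an unknown version."""


def write_recording(rec: ContinuousRecording, events: EventLog, path) -> None:
    """Serialise ``(rec, events)`` to ``path`` (``.npz`` container)."""
    payload = {
        "format_version": np.array(FORMAT_VERSION),
        "data": rec.data,
        "rate": np.array(rec.rate),
        "start_time": np.array(rec.start_time),
        "channel_names": np.array(rec.layout.names),
        "channel_positions": rec.layout.positions,
    }
    for col in EVENT_COLUMNS:
        payload[f"ev_{col}"] = getattr(events, col)
    np.savez_compressed(path, **payload)


def read_recording(path) -> tuple[ContinuousRecording, EventLog]:
    """Load a container written by :func:`write_recording`.

    Raises :class:`RecordingFormatError` naming the offending field when the
    file is missing a required array or carries an unknown version tag.
    """
    with np.load(path, allow_pickle=False) as archive:
        if "format_version" not in archive:
            raise RecordingFormatError("missing field 'format_version'")
        version = str(archive["format_version"])
        if version != FORMAT_VERSION:
            raise RecordingFormatError(
                f"unknown format version {version!r}; expected {FORMAT_VERSION!r}"
            )
        required = ["data", "rate", "start_time", "channel_names",
                    "channel_positions"] + [f"ev_{c}" for c in EVENT_COLUMNS]
        for key in required:
            if key not in archive:
                raise RecordingFormatError(f"missing field {key!r}")
        layout = ChannelLayout(
            tuple(str(n) for n in archive["channel_names"]),
            archive["channel_positions"],
        )
        rec = ContinuousRecording(
            data=archive["data"],
            rate=float(archive["rate"]),
            layout=layout,
            start_time=float(archive["start_time"]),
        )
        events = EventLog(*(archive[f"ev_{c}"] for c in EVENT_COLUMNS))
    return rec, events
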