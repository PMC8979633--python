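"""Electrode montages and scalp geometry.

A :class:`ChannelLayout` couples 10-20 electrode labels with 2-D scalp
coordinates projected onto the unit disc (vertex Cz at the origin, nose
pointing to +y). The default montage is a 16-channel fronto-central /
centro-parietal grid of the kind used for error-potential work with active
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "default_layout", "DECODING_CHANNELS_8"]


@dataclass(frozen=True)
class ChannelLayout:
    """An ordered set of electrodes with unit-disc scalp positions.

    Parameters
    ----------
    names
        Electrode labels (10-20 system), unique.
    positions
        Array of shape ``(n_channels, 2)``; each row within the unit disc.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n_channels, 2)")
        if len(names) != pos.shape[0]:
            raise ValueError(
                f"{len(names)} names but {pos.shape[0]} positions"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if not np.all(np.isfinite(pos)) or np.any(radii > 1.0 + 1e-9):
            raise ValueError("positions must be finite and within the unit disc")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Index of electrode ``name``; raises ``KeyError`` naming it."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def subset(self, names) -> "ChannelLayout":
        """A new layout restricted to ``names``, in the requested order."""
        idx = [self.index(n) for n in names]
        return ChannelLayout(tuple(names), self.positions[idx])

    def neighbor_sets(self, radius: float = 0.22) -> list[list[int]]:
        """Per-channel neighbour indices within ``radius`` (self excluded).

        Used to build nearest-neighbour ("small") Laplacian derivations.
        """
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        out: list[list[int]] = []
        for i in range(len(self)):
            nbr = np.nonzero((d[i] > 1e-12) & (d[i] <= radius))[0]
            out.append(list(nbr))
        return out


# 16-channel fronto-central / centro-parietal montage; x is left(-)/right(+),
# y is anterior(+)/posterior(-), in unit-disc head coordinates.
_DEFAULT_MONTAGE: dict[str, tuple[float, float]] = {
    "Fz": (0.0, 0.40),
    "FC3": (-0.30, 0.20),
    "FC1": (-0.15, 0.20),
    "FCz": (0.0, 0.20),
    "FC2": (0.15, 0.20),
    "FC4": (0.30, 0.20),
    "C3": (-0.40, 0.0),
    "C1": (-0.20, 0.0),
    "Cz": (0.0, 0.0),
    "C2": (0.20, 0.0),
    "C4": (0.40, 0.0),
    "CP1": (-0.15, -0.20),
    "CPz": (0.0, -0.20),
    "CP2": (0.15, -0.20),
    "P1": (-0.20, -0.40),
    "P2": (0.20, -0.40),
}

#: Default 8-channel fronto-central midline subset used for ErrP decoding.
DECODING_CHANNELS_8: tuple[str, ...] = (
    "Fz", "FC1", "FCz", "FC2", "Cz", "CP1", "CPz", "CP2",
)


def default_layout() -> ChannelLayout:
    """The default 16-electrode fronto-central 10-20 montage."""
    names = tuple(_DEFAULT_MONTAGE)
    pos = np.array([_DEFAULT_MONTAGE[n] for n in names], dtype=float)
    return ChannelLayout(names, pos)
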