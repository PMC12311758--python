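"""In-memory container for multichannel EEG recordings.

A :class:`Recording` holds channels x samples data in microvolts together with
the sampling rate, channel labels, optional unit-sphere electrode positions,
bad-channel bookkeeping, condition annotations, and splice points (sample
indices at which non-contiguous segments were concatenated, so that windowed
analyses can avoid straddling a splice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "Annotation"]


@dataclass(frozen=True)
class Annotation:
    """A labelled condition segment: onset and duration in seconds."""

    onset: float
    duration: float
    label: str


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel (10-10 names for scalp EEG).
    positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates (x right, y anterior, z up).
    bad_channels : list of str
        Subset of ``channel_labels`` flagged as bad.
    annotations : list of Annotation
        Condition segments (eyes-open / eyes-closed / hyperventilation ...).
    splices : list of int
        Sample indices where concatenated segments join; windowed metrics
        must not cross them.
    meta : dict
        Free-form metadata (subject id, visit, ground-truth parameters ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    positions: np.ndarray | None = None
    bad_channels: list[str] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    splices: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        unknown = set(self.bad_channels) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"bad_channels not in channel_labels: {sorted(unknown)}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n_channels, 3):
                raise ValueError("positions must be (n_channels, 3)")
            norms = np.linalg.norm(self.positions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("positions must lie on the unit sphere (|r|=1 within 1e-6)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with some fields replaced (data is copied)."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def good_channel_indices(self) -> np.ndarray:
        bad = set(self.bad_channels)
        return np.array(
            [i for i, lab in enumerate(self.channel_labels) if lab not in bad], dtype=int
        )
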