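"""Core containers: multichannel recordings and fixed-length epochs.

A :class:`Recording` is a channels x samples array of scalp potentials in
microvolts together with its sampling rate, 10-20 channel labels, the subject
it came from and the behavioural state label (``"normal"`` or ``"fatigue"``).
An :class:`Epoch` is one fixed-duration window of a recording -- the sample
unit of the classification experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

STATES = ("normal", "fatigue")


@dataclass
class Recording:
    """Multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_names : list of str
        10-20 electrode labels, one per row of ``data``.
    subject_id : str
        Identifier of the subject the recording belongs to.
    state : str
        ``"normal"`` or ``"fatigue"``.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    subject_id: str
    state: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise DataError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.rate > 0:
            raise DataError("rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataError("data contains non-finite samples")
        if self.state not in STATES:
            raise DataError(f"state must be one of {STATES}, got {self.state!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def copy_with(self, data: np.ndarray, rate: float | None = None) -> "Recording":
        """New Recording with replaced data (and optionally rate), same metadata."""
        return Recording(
            data=data,
            rate=self.rate if rate is None else rate,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            state=self.state,
        )


@dataclass
class Epoch:
    """One fixed-duration window of a recording."""

    data: np.ndarray
    rate: float
    subject_id: str
    state: str
    index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("epoch data must be 2-D channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EpochSet:
    """Ordered collection of epochs sharing rate, duration and channel count."""

    epochs: list[Epoch] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            r0, n0, c0 = (
                self.epochs[0].rate,
                self.epochs[0].n_samples,
                self.epochs[0].n_channels,
            )
            for ep in self.epochs:
                if ep.rate != r0 or ep.n_samples != n0 or ep.n_channels != c0:
                    raise DataError("epochs differ in rate, length or channel count")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    @property
    def labels(self) -> np.ndarray:
        """Per-epoch state labels, aligned to ``epochs``."""
        return np.array([ep.state for ep in self.epochs])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([ep.subject_id for ep in self.epochs])

    def extend(self, other: "EpochSet") -> "EpochSet":
        if self.epochs and other.epochs and self.channel_names != other.channel_names:
            raise DataError("cannot merge epoch sets with different channels")
        return EpochSet(
            epochs=self.epochs + other.epochs,
            channel_names=self.channel_names or other.channel_names,
        )
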