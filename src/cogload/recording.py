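"""In-memory container for an event-annotated multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Annotation", "RawRecording"]


@dataclass(frozen=True)
class Annotation:
    """A timestamped event: onset and duration in seconds, free-text label.

    Stimulus events use the compact label
    ``stim <cond>/d<digit>/t<0|1>/r<0|1>`` (condition, digit, target flag,
    responded flag); baseline blocks use ``baseline <cond>`` with the block
    duration.
    """

    onset: float
    duration: float
    description: str


@dataclass
class RawRecording:
    """Signal + sampling rate + annotations + per-channel impedance stream.

    ``data`` is (n_channels, n_samples) in device units.  ``impedance`` is an
    auxiliary stream of the same shape (the device reports one slowly varying
    impedance value per electrode); it rides along through filtering
    untouched and is consulted only by epoch rejection.
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    annotations: list[Annotation] = field(default_factory=list)
    impedance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} signal rows but {len(self.ch_names)} channel names"
            )
        if self.impedance is not None:
            self.impedance = np.asarray(self.impedance, dtype=float)
            if self.impedance.shape != self.data.shape:
                raise ValueError("impedance stream must match data shape")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def pick(self, names) -> "RawRecording":
        """A copy restricted to the given channels, annotations shared."""
        idx = [self.ch_names.index(n) for n in names]
        return RawRecording(
            data=self.data[idx].copy(),
            sfreq=self.sfreq,
            ch_names=tuple(names),
            annotations=list(self.annotations),
            impedance=None if self.impedance is None else self.impedance[idx].copy(),
        )
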