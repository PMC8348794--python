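"""The 14-channel consumer-headset montage and its lobe grouping.

The device covers the scalp with 14 saline electrodes sampled at 128 Hz:
eight frontal, and two each over the temporal, parietal and occipital lobes.
Lobe-averaged statistics and the simulator's load-effect profiles both key on
this grouping, so it lives in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MontageSpec", "DEFAULT_MONTAGE", "CHANNELS", "LOBES"]

CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

LOBES: dict[str, tuple[str, ...]] = {
    "frontal": ("AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6"),
    "temporal": ("T7", "T8"),
    "parietal": ("P7", "P8"),
    "occipital": ("O1", "O2"),
}


@dataclass(frozen=True)
class MontageSpec:
    """Channel names, lobe map and sampling rate of the recording montage."""

    channels: tuple[str, ...] = CHANNELS
    lobes: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(LOBES))
    sfreq: float = 128.0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for lobe, chs in self.lobes.items():
            for ch in chs:
                if ch in seen:
                    raise ValueError(f"channel {ch} mapped to both {seen[ch]} and {lobe}")
                if ch not in self.channels:
                    raise ValueError(f"lobe map references unknown channel {ch}")
                seen[ch] = lobe
        missing = set(self.channels) - set(seen)
        if missing:
            raise ValueError(f"channels not assigned to any lobe: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def lobe_of(self, channel: str) -> str:
        for lobe, chs in self.lobes.items():
            if channel in chs:
                return lobe
        raise KeyError(channel)

    def indices(self, lobe: str) -> list[int]:
        """Positions of a lobe's channels within ``self.channels``."""
        return [self.channels.index(ch) for ch in self.lobes[lobe]]


DEFAULT_MONTAGE = MontageSpec()
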