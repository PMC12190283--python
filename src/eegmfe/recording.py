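"""Core container for one subject's multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: the 19-channel International 10-20 montage used throughout
MONTAGE_10_20 = [
    "Fp1", "F3", "C3", "P3", "O1",
    "Fp2", "F4", "C4", "P4", "O2",
    "F7", "T3", "T5", "F8", "T4", "T6",
    "FZ", "CZ", "PZ",
]

GROUP_HS = "HS"
GROUP_AD = "AD"


class MontageError(KeyError):
    """A requested channel is absent from the recording."""


@dataclass
class Recording:
    """One subject's multichannel signal plus metadata.

    ``data`` is channels x samples in arbitrary microvolt-like units.
    """

    subject_id: str
    group: str
    dataset_id: str
    fs: float
    channel_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

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

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally rate)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)

    def subset(self, montage: list[str]) -> "Recording":
        """Select and reorder channels to match ``montage``."""
        lookup = {name.lower(): i for i, name in enumerate(self.channel_names)}
        try:
            idx = [lookup[name.lower()] for name in montage]
        except KeyError as exc:
            raise MontageError(
                f"channel {exc.args[0]!r} not present in recording "
                f"{self.subject_id!r}"
            ) from exc
        return replace(self, channel_names=list(montage), data=self.data[idx])
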