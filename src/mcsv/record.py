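"""In-memory EEG record model.

An :class:`EEGRecord` holds a channels x samples matrix in microvolts at a
single sampling rate, together with 10-20 montage channel labels and a list
of seizure annotations.  Annotation times are seconds from record start and
spans are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Standard 10-20 labels used for default montages (21 channels).
TEN_TWENTY_21 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "A1", "A2",
]


@dataclass
class SeizureAnnotation:
    """A seizure event: ``[onset, offset)`` in seconds from record start.

    ``channels`` is the subset of channel labels the event was annotated on;
    an empty list means the event applies to all channels.
    """

    onset: float
    offset: float
    label: str = "seiz"
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValueError(
                f"invalid annotation span [{self.onset}, {self.offset})"
            )


@dataclass
class EEGRecord:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    patient_id: str = ""
    annotations: list[SeizureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (200 <= self.fs <= 400):
            warnings.warn(
                f"sampling rate {self.fs} Hz outside the usual 200-400 Hz "
                "scalp-EEG range",
                stacklevel=2,
            )
        for ann in self.annotations:
            if ann.offset > self.duration + 1e-9:
                raise ValueError("annotation extends past end of record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecord":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            annotations=[replace(a, channels=list(a.channels)) for a in self.annotations],
        )
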