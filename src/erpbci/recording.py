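"""In-memory containers for continuous EEG and epoched data.

A :class:`ContinuousRecording` is a channels x samples matrix in microvolts
with a sampling rate, ordered channel labels, a reference description and a
list of stimulus events.  An :class:`EpochSet` is the epochs x channels x
samples array produced by epoching, together with a millisecond time axis,
per-epoch condition labels and a provenance log of the preprocessing steps
that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

#: The study montage: 16 passive electrodes of the modified 10-20 system,
#: in acquisition order.
MONTAGE_16 = (
    "F3", "Fz", "F4", "T7", "T8", "C3", "Cz", "C4",
    "Cp3", "Cp4", "P3", "Pz", "P4", "Po7", "Po8", "Oz",
)

#: Channels posterior to Cz, whose ERP peak sign is inverted for analysis.
POSTERIOR_TO_CZ = ("Cp3", "Cp4", "P3", "Pz", "P4", "Po7", "Po8", "Oz")

#: Frontal channels used by the default ocular-component rule.
FRONTAL_SET = ("F3", "Fz", "F4")


@dataclass
class Event:
    """A stimulus marker: sample index, code and paradigm metadata.

    ``row``/``col`` are the flashed row/column for speller flashes (-1 when
    not applicable); ``is_target`` flags deviant tones and target flashes.
    """

    sample: int
    code: str
    row: int = -1
    col: int = -1
    is_target: bool = False
    duration_samples: int = 0


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), float64, uV
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_16
    events: list[Event] = field(default_factory=list)
    reference: str = "right mastoid"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} channels"
            )
        for ev in self.events:
            if not 0 <= ev.sample < self.data.shape[1]:
                raise InvalidArgumentError(
                    f"event at sample {ev.sample} outside recording "
                    f"of {self.data.shape[1]} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"channel {label!r} not in montage") from None

    def with_data(self, data: np.ndarray, step: str | None = None,
                  reference: str | None = None) -> "ContinuousRecording":
        """Copy of this recording with new sample data and a provenance entry."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            events=list(self.events),
            provenance=prov,
            reference=reference if reference is not None else self.reference,
        )


@dataclass
class EpochSet:
    """Stimulus-locked epochs with condition labels.

    ``data`` is (n_epochs, n_channels, n_samples); ``time`` is the shared
    millisecond axis relative to stimulus onset.  ``baseline_window`` records
    the interval whose per-epoch, per-channel mean was subtracted (``None``
    when no baseline correction was applied, e.g. on the classification path).
    """

    data: np.ndarray
    time: np.ndarray  # ms, length n_samples
    labels: np.ndarray  # per-epoch condition strings
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_16
    baseline_window: tuple[float, float] | None = None
    reference: str = "right mastoid"
    provenance: list[str] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)  # one per retained epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise InvalidArgumentError("data must be epochs x channels x samples")
        if self.data.shape[2] != self.time.size:
            raise InvalidArgumentError("time axis does not match sample count")
        if self.data.shape[0] != self.labels.size:
            raise InvalidArgumentError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"channel {label!r} not in montage") from None
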