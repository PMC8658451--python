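"""Core domain types for the EEG connectivity pipeline.

The pipeline works on epoched multichannel EEG: each subject contributes,
per condition (an eyes-open resting baseline and an active task block),
a set of fixed-duration artifact-free epochs on which spectra, instantaneous
phases and per-epoch networks are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "GROUPS",
    "CONDITIONS",
    "EpochedRecording",
    "StudyDesign",
]

#: Recognized subject groups.
GROUPS = ("typical", "dyslexic")

#: Recognized recording conditions.
CONDITIONS = ("baseline", "task")


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, half-open interval ``[lo, hi)`` in Hz.

    Half-open edges mean a spectral bin sitting exactly on a boundary
    (e.g. 8 Hz between theta and alpha) is counted once, in the upper band.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} [{self.lo}-{self.hi} Hz)"


#: The four classical analysis bands.
DEFAULT_BANDS = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


def get_band(name: str, bands: Sequence[BandSpec] = DEFAULT_BANDS) -> BandSpec:
    """Look up a band by name (case-insensitive)."""
    for b in bands:
        if b.name == name.lower():
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


@dataclass
class EpochedRecording:
    """One subject x condition recording: a stack of equal-shape epochs.

    Parameters
    ----------
    subject_id
        Subject label.
    group
        ``"typical"`` or ``"dyslexic"``.
    condition
        ``"baseline"`` or ``"task"``.
    fs
        Sampling rate in Hz.
    channels
        Ordered, unique channel labels.
    epochs
        Array of shape ``(n_epochs, n_channels, n_samples)``, microvolts.
    band
        Name of the band this recording was filtered to, or ``None`` for
        broadband data. Used to catch misuse (e.g. relative power on
        band-limited input).
    """

    subject_id: str
    group: str
    condition: str
    fs: float
    channels: tuple[str, ...]
    epochs: np.ndarray
    band: str | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.epochs.ndim != 3:
            raise ValueError(
                "epochs must be (n_epochs, n_channels, n_samples), got shape "
                f"{self.epochs.shape}"
            )
        if self.epochs.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.epochs.shape[1]} epoch rows vs {len(self.channels)} "
                "channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    def with_epochs(self, epochs: np.ndarray, band: str | None = None) -> "EpochedRecording":
        """Copy of this recording with replaced epoch data (same metadata)."""
        return EpochedRecording(
            subject_id=self.subject_id,
            group=self.group,
            condition=self.condition,
            fs=self.fs,
            channels=self.channels,
            epochs=epochs,
            band=band if band is not None else self.band,
        )


@dataclass
class StudyDesign:
    """Subjects, group membership, and their per-condition recordings.

    ``recordings`` maps ``(subject_id, condition)`` to an
    :class:`EpochedRecording`. Subjects missing one of the two conditions
    are listed in ``incomplete`` with a reason and are dropped from paired
    (within-subject) analyses but kept for single-condition summaries.
    """

    subjects: list[tuple[str, str]] = field(default_factory=list)
    recordings: dict[tuple[str, str], EpochedRecording] = field(default_factory=dict)
    incomplete: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, group in self.subjects:
            if group not in GROUPS:
                raise ValueError(f"subject {sid!r}: unknown group {group!r}")

    @property
    def groups(self) -> Mapping[str, str]:
        return dict(self.subjects)

    def complete_subjects(self) -> list[tuple[str, str]]:
        """Subjects with both conditions present."""
        return [
            (sid, g)
            for sid, g in self.subjects
            if all((sid, c) in self.recordings for c in CONDITIONS)
        ]

    def iter_recordings(self) -> Iterator[EpochedRecording]:
        yield from self.recordings.values()

    def __len__(self) -> int:
        return len(self.subjects)
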