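"""In-memory containers for multichannel EEG and bipolar derivations.

The central container is :class:`EEGRecord`: per-channel samples in microvolts,
a sampling rate, canonical 10-20 channel labels, and a list of half-open
``[start, end)`` annotations in seconds from record start.  Interhemispheric
synchrony is assessed from homotopic *bipolar* derivations -- difference
signals between two electrodes on the same hemisphere, mirrored left/right
(e.g. C3-O1 vs. C4-O2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MontageError

__all__ = [
    "Annotation",
    "EEGRecord",
    "DerivationPair",
    "STANDARD_PAIRS",
    "make_bipolar",
]


@dataclass(frozen=True)
class Annotation:
    """A tagged half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float
    tag: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"annotation end {self.end} before start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, start: float, end: float) -> bool:
        """True if this annotation intersects the half-open window [start, end)."""
        return self.start < end and start < self.end


@dataclass
class EEGRecord:
    """Multichannel EEG: samples in uV, sampling rate in Hz, 10-20 labels.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    labels
        Canonical 10-20 electrode names, one per channel row.
    annotations
        Tagged half-open intervals (quiet-sleep epochs, artifacts, ...).
    meta
        Free-form provenance (subject id, group label, generator parameters).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for ann in self.annotations:
            if ann.start < 0 or ann.end > self.duration + 1e-9:
                raise ValueError(f"annotation {ann} outside record bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by 10-20 label (case-insensitive)."""
        wanted = label.strip().lower()
        for i, lab in enumerate(self.labels):
            if lab.strip().lower() == wanted:
                return self.data[i]
        raise MontageError(f"electrode {label!r} not present in record "
                           f"(have {', '.join(self.labels)})")

    def annotations_tagged(self, tag: str) -> list[Annotation]:
        return [a for a in self.annotations if a.tag == tag]

    def copy(self) -> "EEGRecord":
        return replace(
            self,
            data=self.data.copy(),
            labels=list(self.labels),
            annotations=list(self.annotations),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class DerivationPair:
    """Homotopic mirror pair of ordered bipolar derivations.

    ``left`` and ``right`` are ordered electrode pairs; the derivation signal
    is anterior minus posterior, e.g. ``("C3", "O1")`` yields C3-O1.
    """

    left: tuple[str, str]
    right: tuple[str, str]

    @property
    def name(self) -> str:
        return (f"{self.left[0]}{self.left[1]}-"
                f"{self.right[0]}{self.right[1]}")

    def swapped(self) -> "DerivationPair":
        return DerivationPair(left=self.right, right=self.left)


#: The five symmetric bipolar combinations conventionally used for
#: interhemispheric synchrony reading: fronto-central, centro-occipital,
#: fronto-occipital, fronto-temporal and temporo-occipital.
STANDARD_PAIRS: tuple[DerivationPair, ...] = (
    DerivationPair(("Fp1", "C3"), ("Fp2", "C4")),
    DerivationPair(("C3", "O1"), ("C4", "O2")),
    DerivationPair(("Fp1", "O1"), ("Fp2", "O2")),
    DerivationPair(("Fp1", "T3"), ("Fp2", "T4")),
    DerivationPair(("T3", "O1"), ("T4", "O2")),
)

#: Centro-occipital pair -- the most stable derivation for ASI.
CENTRO_OCCIPITAL = STANDARD_PAIRS[1]


def make_bipolar(record: EEGRecord, pair: DerivationPair) -> tuple[np.ndarray, np.ndarray]:
    """Build the left and right bipolar derivation signals for ``pair``.

    Returns ``(left, right)`` where each is the anterior-electrode signal
    minus the posterior-electrode signal, in uV, same length as the record.
    Raises :class:`MontageError` naming the first missing electrode.
    """
    left = record.channel(pair.left[0]) - record.channel(pair.left[1])
    right = record.channel(pair.right[0]) - record.channel(pair.right[1])
    return left, right
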