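"""Electrode records and sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Electrode:
    """A single detected contact.

    Coordinates are world mm; ``centroid_mni_mm`` is filled once the
    patient-to-template deformation has been applied.  ``prob_labels``
    maps atlas name to a descending list of (label, voxel fraction) pairs
    over the 10-mm neighbourhood sphere.
    """

    id: int
    centroid_mm: np.ndarray
    centroid_mni_mm: np.ndarray | None = None
    radius_mm: float = 1.3
    mean_intensity: float = float("nan")
    label: str | None = None
    channel: int | None = None
    tissue_class: str | None = None  # gray | white | unknown | None
    atlas_labels: dict = field(default_factory=dict)
    prob_labels: dict = field(default_factory=dict)
    original_mm: np.ndarray | None = None  # position before projection/nudges

    def __post_init__(self) -> None:
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)
        if self.centroid_mni_mm is not None:
            self.centroid_mni_mm = np.asarray(self.centroid_mni_mm, dtype=float)
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


class ElectrodeSet:
    """Ordered collection of electrodes with unique channel numbers."""

    def __init__(self, electrodes=()):
        self.electrodes: list[Electrode] = list(electrodes)
        chans = [e.channel for e in self.electrodes if e.channel is not None]
        if len(chans) != len(set(chans)):
            dupes = sorted({c for c in chans if chans.count(c) > 1})
            raise ValueError(f"duplicate channel numbers: {dupes}")

    def __len__(self) -> int:
        return len(self.electrodes)

    def __iter__(self):
        return iter(self.electrodes)

    def __getitem__(self, i) -> Electrode:
        return self.electrodes[i]

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.centroid_mm for e in self.electrodes]).reshape(-1, 3)

    def by_label(self, label: str) -> Electrode:
        for e in self.electrodes:
            if e.label == label:
                return e
        raise KeyError(label)

    def sorted_by_channel(self) -> "ElectrodeSet":
        unassigned = [e.label or e.id for e in self.electrodes if e.channel is None]
        if unassigned:
            raise ValueError(f"electrodes without channel assignment: {unassigned}")
        return ElectrodeSet(sorted(self.electrodes, key=lambda e: e.channel))
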