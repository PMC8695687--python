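"""Electrode contact detection in postimplant CT.

Metal contacts show up as very bright blobs.  Detection thresholds the
CT at 21 levels spread over the 99th–100th intensity percentile range,
keeps connected components that are plausibly contact-sized and lie
inside the projection surface, and picks the threshold at the center of
the widest stable stretch of the detection-count curve.  Contact centers
are intensity-weighted centroids of the supra-threshold voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .electrodes import Electrode, ElectrodeSet
from .surfaces import Surface, interior_mask
from .volumes import Volume

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class DetectionConfig:
    """Tunables for automatic detection (defaults follow the published
    procedure: 21 thresholds over the 99th–100th percentile, component
    volume in (6 voxels, volume of a 2-mm sphere), stability delta 5,
    1-mm duplicate cleanup, 250-contact cap, 1.3-mm contact radius)."""

    n_thresholds: int = 21
    pct_lo: float = 99.0
    pct_hi: float = 100.0
    min_voxels: int = 6
    max_volume_mm3: float = 4.0 / 3.0 * math.pi * 2.0**3
    stability_delta: int = 5
    min_separation_mm: float = 1.0
    max_electrodes: int = 250
    electrode_radius_mm: float = 1.3
    manual_cube_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.pct_lo >= self.pct_hi:
            raise ValueError("pct_lo must be below pct_hi")
        if self.n_thresholds < 2:
            raise ValueError("need at least 2 thresholds")
        if min(self.min_voxels, self.max_electrodes) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class Component:
    """Connected supra-threshold component (candidate contact)."""

    voxel_indices: np.ndarray  # (n, 3) integer grid indices
    volume_mm3: float
    mean_intensity: float
    weighted_centroid_mm: np.ndarray


@dataclass
class DetectionResult:
    electrodes: ElectrodeSet
    optimal_threshold_hu: float
    curve: list = field(default_factory=list)  # [(threshold_hu, n_detected)]


def extract_components(
    ct: Volume, threshold_hu: float, inside: Volume, cfg: DetectionConfig | None = None
) -> list[Component]:
    """Contact-sized components of (ct > threshold) with 26-connectivity.

    A component is kept iff its intensity-weighted centroid falls on an
    inside-mask voxel, its voxel count exceeds ``min_voxels`` and its
    volume is below ``max_volume_mm3``.
    """
    cfg = cfg or DetectionConfig()
    if ct.shape != inside.shape:
        raise ValueError("ct and inside mask are not on the same grid")
    mask = ct.data > threshold_hu
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    vox_vol = ct.voxel_volume_mm3
    ok_size = (counts > cfg.min_voxels) & (counts * vox_vol < cfg.max_volume_mm3)
    comps: list[Component] = []
    if not np.any(ok_size):
        return comps
    data = np.asarray(ct.data, dtype=float)
    centroids = ndimage.center_of_mass(data, labels, idx[ok_size])
    means = ndimage.mean(data, labels, idx[ok_size])
    inside_data = np.asarray(inside.data).astype(bool)
    objects = ndimage.find_objects(labels)
    for lab, cnt, cen, mean in zip(idx[ok_size], counts[ok_size], centroids, means):
        cen_vox = np.clip(
            np.round(cen).astype(int), 0, np.array(ct.shape) - 1
        )
        if not inside_data[tuple(cen_vox)]:
            continue
        sl = objects[lab - 1]
        offset = np.array([s.start for s in sl])
        vox = np.argwhere(labels[sl] == lab) + offset
        comps.append(
            Component(
                voxel_indices=vox,
                volume_mm3=float(cnt * vox_vol),
                mean_intensity=float(mean),
                weighted_centroid_mm=np.asarray(ct.index_to_world(cen), dtype=float),
            )
        )
    return comps


def _cleanup_close(comps: list[Component], min_sep_mm: float) -> list[Component]:
    """Greedy duplicate removal: walk components by descending mean
    intensity and drop any whose centroid lies within ``min_sep_mm`` of
    an already-kept one."""
    order = sorted(comps, key=lambda c: -c.mean_intensity)
    kept: list[Component] = []
    for c in order:
        if all(
            np.linalg.norm(c.weighted_centroid_mm - k.weighted_centroid_mm)
            >= min_sep_mm
            for k in kept
        ):
            kept.append(c)
    return kept


def detection_thresholds(ct: Volume, cfg: DetectionConfig) -> np.ndarray:
    lo, hi = np.percentile(ct.data, [cfg.pct_lo, cfg.pct_hi])
    return np.linspace(lo, hi, cfg.n_thresholds)


def stable_segments(counts, delta: int) -> list[tuple[int, int]]:
    """Maximal runs [i, j] (inclusive) where consecutive detection counts
    change by at most ``delta``."""
    segs = []
    start = 0
    for i in range(1, len(counts)):
        if abs(counts[i] - counts[i - 1]) > delta:
            segs.append((start, i - 1))
            start = i
    segs.append((start, len(counts) - 1))
    return segs


def choose_optimal_threshold(thresholds, counts, delta: int) -> int:
    """Index of the optimal threshold: center element (lower-middle on
    even length) of the stable segment with the largest per-threshold
    count; ties break to the longer segment, then the lower threshold."""
    segs = stable_segments(counts, delta)
    counts = np.asarray(counts)

    def key(seg):
        i, j = seg
        return (-counts[i : j + 1].max(), -(j - i), i)

    i, j = min(segs, key=key)
    return (i + j) // 2


def auto_detect(
    ct: Volume,
    projection: Surface,
    cfg: DetectionConfig | None = None,
    inside: Volume | None = None,
) -> DetectionResult:
    """Full automatic detection: threshold sweep, stability-based
    threshold choice, 1-mm duplicate cleanup and intensity-ranked cap.

    ``inside`` may pass a precomputed interior mask of the projection
    surface on the CT grid to skip the voxelization step.
    """
    cfg = cfg or DetectionConfig()
    if inside is None:
        inside = interior_mask(projection, ct)
    thresholds = detection_thresholds(ct, cfg)
    per_threshold: list[list[Component]] = [
        extract_components(ct, t, inside, cfg) for t in thresholds
    ]
    counts = [len(c) for c in per_threshold]
    curve = list(zip((float(t) for t in thresholds), counts))
    if not any(counts):
        return DetectionResult(ElectrodeSet(), float("nan"), curve)
    best = choose_optimal_threshold(thresholds, counts, cfg.stability_delta)
    comps = _cleanup_close(per_threshold[best], cfg.min_separation_mm)
    comps = comps[: cfg.max_electrodes]  # already intensity-sorted
    electrodes = ElectrodeSet(
        Electrode(
            id=i,
            centroid_mm=c.weighted_centroid_mm,
            radius_mm=cfg.electrode_radius_mm,
            mean_intensity=c.mean_intensity,
        )
        for i, c in enumerate(comps)
    )
    return DetectionResult(electrodes, float(thresholds[best]), curve)


def manual_detect(
    ct: Volume,
    click_mm,
    threshold_hu: float,
    cfg: DetectionConfig | None = None,
    manual_draw: bool = False,
) -> Electrode:
    """Place one contact near a clicked point.

    With ``manual_draw`` the contact sits exactly at the click; otherwise
    the CT is thresholded inside a cube of side 6x the contact radius
    around the click and the nearest component's weighted centroid wins.
    """
    cfg = cfg or DetectionConfig()
    click_mm = np.asarray(click_mm, dtype=float)
    if manual_draw:
        return Electrode(id=0, centroid_mm=click_mm, radius_mm=cfg.electrode_radius_mm)
    half_mm = cfg.manual_cube_factor * cfg.electrode_radius_mm / 2.0
    center_vox = ct.world_to_index(click_mm)
    half_vox = np.ceil(half_mm / ct.voxel_sizes).astype(int)
    lo = np.maximum(0, np.round(center_vox).astype(int) - half_vox)
    hi = np.minimum(np.array(ct.shape), np.round(center_vox).astype(int) + half_vox + 1)
    if np.any(lo >= hi):
        raise ValueError("no component near click: cube outside field of view")
    sub = np.asarray(ct.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]], dtype=float)
    labels, n = ndimage.label(sub > threshold_hu, structure=_CONN26)
    if n == 0:
        raise ValueError("no component near click")
    centroids = ndimage.center_of_mass(sub, labels, np.arange(1, n + 1))
    cents_mm = np.array(
        [ct.index_to_world(np.asarray(c) + lo) for c in centroids]
    ).reshape(-1, 3)
    means = ndimage.mean(sub, labels, np.arange(1, n + 1))
    nearest = int(np.argmin(np.linalg.norm(cents_mm - click_mm, axis=1)))
    return Electrode(
        id=0,
        centroid_mm=cents_mm[nearest],
        radius_mm=cfg.electrode_radius_mm,
        mean_intensity=float(means[nearest]),
    )
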