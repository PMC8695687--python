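"""Tissue classification and anatomical atlas labeling.

Each contact is modelled as a 1.3-mm sphere of voxels.  Gray/white
class comes from a two-sided Wilcoxon rank-sum test between the gray and
white tissue-probability values inside that sphere (p < 0.001 assigns
the higher-median class; otherwise gray by default; contacts whose mean
probability is below 0.1 for both maps are "unknown").  Anatomical
labels come from warping the sphere voxels to template (MNI) space with
a non-linear deformation field and taking the modal atlas label, plus a
probabilistic label list over a 1-cm sphere.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .electrodes import Electrode
from .volumes import Volume

UNLABELLED = "unlabelled"


@dataclass
class LabelConfig:
    sphere_radius_mm: float = 1.3
    prob_radius_mm: float = 10.0
    prob_exclude_frac: float = 0.05
    p_threshold: float = 0.001
    unknown_mean_threshold: float = 0.1
    count_background: bool = True

    def __post_init__(self) -> None:
        if self.sphere_radius_mm <= 0 or self.prob_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.prob_exclude_frac < 1:
            raise ValueError("prob_exclude_frac must be in (0, 1)")


@dataclass
class DeformationField:
    """Voxel-wise absolute coordinate map between patient and MNI spaces.

    ``values`` has shape (X, Y, Z, 3): for each voxel of the source grid
    (defined by ``affine``), the corresponding coordinate in the target
    space, in mm (absolute coordinates, not displacements).  ``direction``
    is "patient_to_mni" (source grid in patient space, values in MNI mm;
    the analog of SPM's iy_MR.nii as used for point warping) or
    "mni_to_patient" (source grid in MNI space, values in patient mm).
    """

    values: np.ndarray
    affine: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise ValueError("deformation field must be (X, Y, Z, 3)")
        if self.direction not in ("patient_to_mni", "mni_to_patient"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def shape(self):
        return self.values.shape[:3]


@dataclass
class AtlasVolume:
    """Integer label volume in MNI space plus its label table.

    The table maps label index -> name; index 0 is reserved for
    background/unlabelled tissue.
    """

    labels: Volume
    table: dict
    name: str = "atlas"

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.labels.data).dtype, np.integer):
            raise ValueError("atlas volume must be integer-valued")
        present = np.unique(np.asarray(self.labels.data))
        missing = [int(i) for i in present if i != 0 and int(i) not in self.table]
        if missing:
            raise ValueError(f"atlas indices without table entry: {missing}")

    def label_name(self, index: int) -> str:
        if index == 0:
            return UNLABELLED
        return self.table[int(index)]


def load_atlas(nii_path, table_path, name: str | None = None) -> AtlasVolume:
    """Load an MNI-registered atlas: NIfTI labels + tab-delimited table
    of ``index<TAB>name`` rows."""
    from .volumes import load_volume
    import pathlib

    vol = load_volume(nii_path, space_tag="mni")
    vol = Volume(np.rint(np.asarray(vol.data)).astype(np.int32), vol.affine, "mni")
    df = pd.read_csv(table_path, sep="\t", header=None, names=["index", "name"])
    table = {int(r["index"]): str(r["name"]) for _, r in df.iterrows()}
    return AtlasVolume(vol, table, name=name or pathlib.Path(nii_path).stem)


def save_atlas_table(table: dict, path) -> None:
    with open(path, "w") as fh:
        for idx in sorted(table):
            fh.write(f"{idx}\t{table[idx]}\n")


# ---------------------------------------------------------------------------
# Sphere sampling


def sphere_voxels(center_mm, radius_mm: float, grid: Volume) -> np.ndarray:
    """Indices (n, 3) of grid voxels whose centers lie within radius_mm
    of center_mm (world distance); empty if the sphere misses the grid."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center_mm = np.asarray(center_mm, dtype=float)
    cvox = grid.world_to_index(center_mm)
    half = radius_mm / grid.voxel_sizes
    lo = np.maximum(0, np.floor(cvox - half).astype(int))
    hi = np.minimum(np.array(grid.shape), np.ceil(cvox + half).astype(int) + 1)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    ii, jj, kk = np.meshgrid(
        *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    keep = np.linalg.norm(world - center_mm, axis=1) <= radius_mm
    return idx[keep]


# ---------------------------------------------------------------------------
# Rank-sum test


def _ranksum_statistic(pooled_ranks: np.ndarray, nx: int) -> float:
    return float(np.sum(pooled_ranks[:nx]))


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration when both samples have <= 10 values
    (ties handled through midranks); otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(np.sum(ranks[:nx]))
    mu = nx * (nx + ny + 1) / 2.0
    if nx <= 10 and ny <= 10:
        # exact: enumerate every split of the pooled midranks
        dev = abs(w - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            ws = ranks[list(comb)].sum()
            if abs(ws - mu) >= dev - 1e-12:
                count += 1
            total += 1
        return count / total
    # normal approximation with tie and continuity corrections
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
    return min(1.0, float(2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Gray/white classification


def classify_gray_white(
    e: Electrode, gm: Volume, wm: Volume, cfg: LabelConfig | None = None
) -> str:
    """Tissue class for one contact: 'gray', 'white' or 'unknown'.

    The unknown rule (both sphere means < 0.1) is checked first so that
    out-of-brain contacts never reach the test; otherwise a significant
    rank-sum test assigns the higher-median class, and gray is the
    default when the test is not significant.
    """
    cfg = cfg or LabelConfig()
    if gm.shape != wm.shape or not np.allclose(gm.affine, wm.affine):
        raise ValueError("gray and white maps are not on the same grid")
    vox = sphere_voxels(e.centroid_mm, e.radius_mm, gm)
    if len(vox) == 0:
        import warnings

        warnings.warn("electrode sphere outside tissue maps; class unknown")
        return "unknown"
    gx = np.asarray(gm.data, float)[vox[:, 0], vox[:, 1], vox[:, 2]]
    wx = np.asarray(wm.data, float)[vox[:, 0], vox[:, 1], vox[:, 2]]
    if gx.mean() < cfg.unknown_mean_threshold and wx.mean() < cfg.unknown_mean_threshold:
        return "unknown"
    p = rank_sum_p(gx, wx)
    if p < cfg.p_threshold:
        return "gray" if np.median(gx) >= np.median(wx) else "white"
    return "gray"


# ---------------------------------------------------------------------------
# Deformation fields and atlas labels


def warp_points(points, field: DeformationField) -> np.ndarray:
    """Map points through a deformation field by trilinear interpolation
    of the stored target coordinates.  Points are in the field's source
    space (patient mm for a patient_to_mni field)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(field.affine)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    shape = np.array(field.shape)
    bad = np.any((idx < -0.5) | (idx > shape - 0.5), axis=1)
    if np.any(bad):
        raise ValueError(
            f"points outside deformation field domain: {pts[bad].tolist()}"
        )
    out = np.empty_like(pts)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.values[..., c], idx.T, order=1, mode="nearest"
        )
    return out


def _modal_label(values: np.ndarray, count_background: bool) -> int:
    vals, counts = np.unique(values, return_counts=True)
    if not count_background:
        keep = vals != 0
        vals, counts = vals[keep], counts[keep]
        if len(vals) == 0:
            return 0
    best = counts.max()
    return int(vals[counts == best].min())  # ties -> lower label index


def assign_atlas_labels(
    e: Electrode,
    atlas: AtlasVolume,
    field: DeformationField,
    cfg: LabelConfig | None = None,
    grid: Volume | None = None,
):
    """Modal atlas label over the warped contact sphere, plus the
    descending per-label fraction list over the warped 1-cm sphere.

    ``grid`` is the patient-space grid defining sphere voxels (defaults
    to the field's own grid).  Background counts toward the mode; if it
    wins, the contact is 'unlabelled'.
    """
    cfg = cfg or LabelConfig()
    if field.direction != "patient_to_mni":
        raise ValueError("atlas labeling needs a patient_to_mni field")
    if grid is None:
        grid = Volume(field.values[..., 0], field.affine, space_tag="patient")
    adata = np.asarray(atlas.labels.data)
    ainv = np.linalg.inv(atlas.labels.affine)

    def sphere_labels(radius):
        vox = sphere_voxels(e.centroid_mm, radius, grid)
        if len(vox) == 0:
            return np.empty(0, dtype=adata.dtype)
        world = vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
        mni = warp_points(world, field)
        aidx = np.rint(mni @ ainv[:3, :3].T + ainv[:3, 3]).astype(int)
        inb = np.all((aidx >= 0) & (aidx < np.array(adata.shape)), axis=1)
        labels = np.zeros(len(aidx), dtype=adata.dtype)  # outside atlas -> background
        labels[inb] = adata[aidx[inb, 0], aidx[inb, 1], aidx[inb, 2]]
        return labels

    contact_labels = sphere_labels(cfg.sphere_radius_mm)
    if len(contact_labels) == 0:
        modal_name = UNLABELLED
    else:
        modal = _modal_label(contact_labels, cfg.count_background)
        modal_name = atlas.label_name(modal)

    prob_labels_raw = sphere_labels(cfg.prob_radius_mm)
    prob_list = []
    if len(prob_labels_raw):
        vals, counts = np.unique(prob_labels_raw, return_counts=True)
        fracs = counts / counts.sum()
        order = np.argsort(-fracs, kind="stable")
        prob_list = [
            (atlas.label_name(int(vals[i])), float(fracs[i])) for i in order
        ]
    return modal_name, prob_list


def matching_labels(prob_list, cfg: LabelConfig | None = None) -> list:
    """Probabilistic labels retained for matching: entries occupying at
    least ``prob_exclude_frac`` (default 5%) of the 1-cm sphere."""
    cfg = cfg or LabelConfig()
    return [(name, frac) for name, frac in prob_list if frac >= cfg.prob_exclude_frac]


def warp_atlas_to_patient(
    atlas: AtlasVolume, field: DeformationField, grid: Volume
) -> Volume:
    """Pull an MNI atlas into patient space: each patient-grid voxel is
    sent through the patient->MNI field and takes the nearest-neighbour
    atlas label there.  Conventionally saved with an 'lw' name prefix.
    """
    if field.direction != "patient_to_mni":
        raise ValueError("atlas warping needs a patient_to_mni field")
    shape = grid.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    mni = warp_points(world, field)
    adata = np.asarray(atlas.labels.data)
    ainv = np.linalg.inv(atlas.labels.affine)
    aidx = np.rint(mni @ ainv[:3, :3].T + ainv[:3, 3]).astype(int)
    inb = np.all((aidx >= 0) & (aidx < np.array(adata.shape)), axis=1)
    out = np.zeros(len(aidx), dtype=np.int32)
    out[inb] = adata[aidx[inb, 0], aidx[inb, 1], aidx[inb, 2]]
    return Volume(out.reshape(shape), grid.affine, space_tag="patient")
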