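"""Volume I/O and rigid-body geometry.

All world coordinates are RAS millimetres (+x right, +y anterior, +z
superior); voxel indices are 0-based and the affine maps voxel index to
world mm.  Images are kept as :class:`Volume` objects — a scalar 3-D array
plus its 4x4 affine — the same minimal container nibabel exposes, with a
``space_tag`` distinguishing patient-space from template (MNI) volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a file or affine does not satisfy the format contract."""


@dataclass
class Volume:
    """A scalar 3-D image with a voxel-index -> world-mm affine.

    ``data`` holds Hounsfield units for CT, arbitrary intensity for MRI,
    probabilities in [0, 1] for tissue maps, or integer labels for atlases.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "patient"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3-D volume, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if self.space_tag not in ("patient", "mni"):
            raise ValueError(f"unknown space_tag {self.space_tag!r}")

    # -- basic geometry helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel in mm along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (pts @ inv[:3, :3].T + inv[:3, 3]).squeeze()

    def sample_world(self, pts: np.ndarray, order: int = 1, cval=None) -> np.ndarray:
        """Interpolate the volume at world-mm points (trilinear by default)."""
        idx = np.atleast_2d(self.world_to_index(pts))
        if cval is None:
            cval = float(np.min(self.data))
        return ndimage.map_coordinates(
            self.data.astype(float), idx.T, order=order, mode="constant", cval=cval
        )


@dataclass
class RigidTransform:
    """Proper rigid motion: p -> rotation @ p + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation determinant must be +1")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts @ self.rotation.T + self.translation).squeeze()

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class AcpcLandmarks:
    """Anterior commissure, posterior commissure and a midsagittal point (mm)."""

    ac: np.ndarray
    pc: np.ndarray
    ms: np.ndarray

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        self.ms = np.asarray(self.ms, dtype=float)
        if np.linalg.norm(self.ac - self.pc) <= 0:
            raise ValueError("AC and PC coincide")


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path, space_tag: str = "patient") -> Volume:
    """Load a 3-D NIfTI-1/2 volume; data and affine are taken verbatim.

    No reorientation or rescaling is applied here — use
    :func:`reorient_to_ras` / :func:`resample_isotropic` afterwards.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    affine = img.affine
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise FormatError(f"missing or singular affine in {path}")
    return Volume(data, np.asarray(affine, dtype=float), space_tag=space_tag)


def save_volume(v: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data), v.affine), str(path))


# ---------------------------------------------------------------------------
# Orientation and resampling


def reorient_to_ras(v: Volume) -> Volume:
    """Permute/flip axes so the affine's 3x3 block is diagonal-dominant
    with a positive diagonal (RAS).  The world position of every voxel is
    unchanged; only storage order and the affine change."""
    ornt = nib.orientations.io_orientation(v.affine)
    if np.any(np.isnan(ornt)):
        raise ValueError("cannot determine axis permutation for oblique affine")
    target = np.array([[0, 1], [1, 1], [2, 1]], dtype=float)
    if np.array_equal(ornt, target):
        return v
    xfm = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(v.data, xfm)
    affine = v.affine @ nib.orientations.inv_ornt_aff(xfm, v.data.shape)
    return Volume(data, affine, space_tag=v.space_tag)


def resample_isotropic(
    v: Volume, resolution_mm: float = 0.4, order: int = 3, cval=None
) -> Volume:
    """Resample onto an isotropic grid (default 0.4 mm) with cubic
    interpolation, preserving the field of view to within one output voxel."""
    if resolution_mm <= 0:
        raise ValueError("resolution_mm must be positive")
    old_sizes = v.voxel_sizes
    new_shape = np.maximum(1, np.ceil(np.array(v.shape) * old_sizes / resolution_mm))
    new_affine = v.affine.copy()
    scale = np.diag(resolution_mm / old_sizes)
    new_affine[:3, :3] = v.affine[:3, :3] @ scale
    return _reslice(v, new_affine, tuple(int(n) for n in new_shape), order=order, cval=cval)


def _reslice(v: Volume, target_affine, target_shape, order=3, cval=None) -> Volume:
    """Sample ``v`` onto the grid defined by target_affine/target_shape."""
    if cval is None:
        cval = float(np.min(v.data))
    mat = np.linalg.inv(v.affine) @ np.asarray(target_affine, dtype=float)
    out = ndimage.affine_transform(
        v.data.astype(float),
        mat[:3, :3],
        offset=mat[:3, 3],
        output_shape=target_shape,
        order=order,
        mode="constant",
        cval=cval,
    )
    return Volume(out, np.asarray(target_affine, dtype=float), space_tag=v.space_tag)


# ---------------------------------------------------------------------------
# ACPC alignment


def compute_acpc_transform(lm: AcpcLandmarks) -> RigidTransform:
    """Rigid transform into the ACPC frame.

    Convention: AC maps to the origin; the AC–PC line becomes the y axis
    with PC at negative y (anterior positive); the midsagittal plane
    through AC, PC and MS becomes x = 0; z completes a right-handed frame
    (superior positive for an MS point above the AC–PC line).
    """
    y = lm.ac - lm.pc
    y = y / np.linalg.norm(y)
    m = lm.ms - lm.ac
    x = np.cross(y, m)
    nx = np.linalg.norm(x)
    if nx < 1e-9 * max(np.linalg.norm(m), 1.0) or np.linalg.norm(m) == 0:
        raise ValueError("midsagittal point collinear with AC-PC")
    x = x / nx
    z = np.cross(x, y)
    rot = np.vstack([x, y, z])  # rows: target axes in world coords
    return RigidTransform(rot, -rot @ lm.ac)


def apply_rigid(
    v: Volume, t: RigidTransform, order: int = 3, cval=None
) -> Volume:
    """Reslice ``v`` under a rigid motion of its content.

    The output stays on the input grid; a voxel at world p takes the value
    the moved image has there, i.e. the input sampled at t^-1(p).
    Out-of-field voxels are filled with ``cval`` (default: the input
    minimum, so padding never creates spurious bright voxels).
    """
    inv = t.inverse()
    target_affine = v.affine.copy()
    target_affine[:3, :3] = inv.rotation @ v.affine[:3, :3]
    target_affine[:3, 3] = inv.apply(v.affine[:3, 3])
    out = _reslice(v, target_affine, v.shape, order=order, cval=cval)
    return Volume(out.data, v.affine, space_tag=v.space_tag)
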