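"""Brain and projection surfaces.

Two triangulated envelopes are built from the gray+white tissue
probability maps: a *brain surface* (light 3-mm box smoothing) used for
display and interior tests, and a heavily smoothed *projection surface*
(10-mm box smoothing) onto which brain-shifted surface electrodes are
projected.  Both are isosurfaces at level 0.3 of the smoothed binary
brain mask, in world millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure
from sklearn.cluster import DBSCAN

from . import _trimath
from .volumes import Volume


@dataclass
class SurfaceConfig:
    mask_threshold: float = 0.95
    iso_level: float = 0.3
    brain_smooth_mm: float = 3.0
    projection_smooth_mm: float = 10.0
    dbscan_eps_edge_factor: float = 3.0  # eps = factor x median edge length
    dbscan_min_pts: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.iso_level < 1:
            raise ValueError("iso_level must be in (0, 1)")
        if not 0 < self.mask_threshold <= 1:
            raise ValueError("mask_threshold must be in (0, 1]")
        if self.brain_smooth_mm <= 0 or self.projection_smooth_mm <= 0:
            raise ValueError("smoothing widths must be positive")


@dataclass
class Surface:
    """Triangulated mesh in world mm; ``kind`` is 'brain' or 'projection'."""

    vertices: np.ndarray
    faces: np.ndarray
    kind: str = "brain"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def median_edge_length(self) -> float:
        tm = self.as_trimesh()
        return float(np.median(tm.edges_unique_length))

    # -- serialization -----------------------------------------------------
    def save_ply(self, path) -> None:
        self.as_trimesh().export(str(path), file_type="ply", encoding="ascii")

    @staticmethod
    def load_ply(path, kind: str = "brain") -> "Surface":
        tm = trimesh.load(str(path), file_type="ply", process=False)
        return Surface(np.asarray(tm.vertices), np.asarray(tm.faces), kind=kind)


def save_surface_pair(brain: Surface, projection: Surface, outdir) -> None:
    """Export both surfaces as ASCII PLY plus a small JSON manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    brain.save_ply(outdir / "brain.ply")
    projection.save_ply(outdir / "projection.ply")
    manifest = {
        "brain": {"file": "brain.ply", "n_vertices": len(brain.vertices)},
        "projection": {
            "file": "projection.ply",
            "n_vertices": len(projection.vertices),
        },
        "units": "mm",
    }
    (outdir / "surfaces.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Mask and isosurface


def make_brain_mask(gm: Volume, wm: Volume, cfg: SurfaceConfig | None = None) -> Volume:
    """Binary brain mask: (gm + wm) > threshold, largest 26-connected
    component only (detached satellites — skull fragments, noise — drop)."""
    cfg = cfg or SurfaceConfig()
    if gm.shape != wm.shape or not np.allclose(gm.affine, wm.affine):
        raise ValueError("gray and white maps are not on the same grid")
    mask = (np.asarray(gm.data, float) + np.asarray(wm.data, float)) > cfg.mask_threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return Volume(mask.astype(np.uint8), gm.affine, space_tag=gm.space_tag)


def _box_smooth(mask_data: np.ndarray, smooth_mm: float, voxel_mm: float) -> np.ndarray:
    width = int(round(smooth_mm / voxel_mm))
    width = max(1, width)
    if width % 2 == 0:
        width += 1
    return ndimage.uniform_filter(mask_data.astype(float), size=width)


def generate_surface(
    mask: Volume, smooth_mm: float, iso_level: float = 0.3, kind: str = "brain"
) -> Surface:
    """Box-smooth a binary mask and extract the marching-cubes isosurface.

    The cuboid kernel width is round(smooth_mm / voxel_mm) forced odd.
    Vertices are mapped to world mm through the mask affine; faces are
    wound so normals point outward.
    """
    if smooth_mm <= 0:
        raise ValueError("smooth_mm must be positive")
    data = np.asarray(mask.data, dtype=float)
    if not np.any(data):
        raise ValueError("no surface: mask is empty")
    voxel_mm = float(np.mean(mask.voxel_sizes))
    smoothed = _box_smooth(data, smooth_mm, voxel_mm)
    # pad so a mask touching the grid boundary still yields a closed mesh
    smoothed = np.pad(smoothed, 1, mode="constant", constant_values=0.0)
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=iso_level)
    verts -= 1.0  # undo padding offset
    verts_mm = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    tm = trimesh.Trimesh(verts_mm, faces, process=False)
    tm.fix_normals()
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return Surface(np.asarray(tm.vertices), np.asarray(tm.faces), kind=kind)


def remove_remnants(
    s: Surface, eps_mm: float | None = None, min_pts: int = 10
) -> Surface:
    """Drop enclosed surface remnants (e.g. ventricle shells) by density
    clustering of the vertices and keeping only the largest cluster.

    ``eps_mm`` defaults to 3x the median mesh edge length.  Ties on
    cluster size break to the cluster containing the lowest vertex index.
    """
    if len(s.vertices) == 0:
        raise ValueError("empty surface")
    if eps_mm is None:
        eps_mm = 3.0 * s.median_edge_length()
    labels = DBSCAN(eps=eps_mm, min_samples=min_pts).fit_predict(s.vertices)
    valid = labels >= 0
    if not np.any(valid):
        raise ValueError("no dominant cluster: all vertices classified as noise")
    sizes = np.bincount(labels[valid])
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # lowest minimum vertex index wins
        first_idx = [int(np.flatnonzero(labels == b)[0]) for b in best]
        keep_label = int(best[int(np.argmin(first_idx))])
    else:
        keep_label = int(best[0])
    keep = labels == keep_label
    new_index = -np.ones(len(s.vertices), dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    face_keep = keep[s.faces].all(axis=1)
    faces = new_index[s.faces[face_keep]]
    return Surface(s.vertices[keep], faces, kind=s.kind)


def build_surfaces(
    gm: Volume, wm: Volume, cfg: SurfaceConfig | None = None
) -> tuple[Surface, Surface]:
    """Convenience pipeline: mask -> (brain surface, projection surface)."""
    cfg = cfg or SurfaceConfig()
    mask = make_brain_mask(gm, wm, cfg)
    brain = remove_remnants(
        generate_surface(mask, cfg.brain_smooth_mm, cfg.iso_level, kind="brain"),
        min_pts=cfg.dbscan_min_pts,
    )
    projection = remove_remnants(
        generate_surface(
            mask, cfg.projection_smooth_mm, cfg.iso_level, kind="projection"
        ),
        min_pts=cfg.dbscan_min_pts,
    )
    return brain, projection


# ---------------------------------------------------------------------------
# Interior test and nearest point


def interior_mask(s: Surface, grid: Volume) -> Volume:
    """Binary volume marking grid voxels whose centers lie inside the
    closed mesh (parity of triangle crossings along grid columns)."""
    if not s.is_closed:
        raise ValueError("surface not closed")
    inv = np.linalg.inv(grid.affine)
    verts = s.vertices @ inv[:3, :3].T + inv[:3, 3]
    # tiny irrational shift so rays through integer columns never hit
    # triangle edges/vertices exactly
    verts = verts + np.array([3.7e-5, 2.3e-5, 1.1e-5])
    tri = verts[s.faces]  # (F, 3, 3) in voxel index coords
    nx, ny, nz = grid.shape

    ax, ay = tri[:, :, 0], tri[:, :, 1]
    lo_x = np.floor(ax.min(axis=1)).astype(np.int64)
    lo_y = np.floor(ay.min(axis=1)).astype(np.int64)
    max_span = 0
    if len(tri):
        max_span = int(
            np.ceil(
                max(
                    (ax.max(axis=1) - ax.min(axis=1)).max(),
                    (ay.max(axis=1) - ay.min(axis=1)).max(),
                )
            )
        )
    cols: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    for di in range(max_span + 2):
        for dj in range(max_span + 2):
            px = lo_x + di  # candidate integer column x
            py = lo_y + dj
            inside_bbox = (
                (px >= ax.min(axis=1))
                & (px <= ax.max(axis=1))
                & (py >= ay.min(axis=1))
                & (py <= ay.max(axis=1))
                & (px >= 0)
                & (px < nx)
                & (py >= 0)
                & (py < ny)
            )
            if not np.any(inside_bbox):
                continue
            t = tri[inside_bbox]
            qx = px[inside_bbox].astype(float)
            qy = py[inside_bbox].astype(float)
            # 2-D barycentric test in the xy projection
            x0, y0 = t[:, 0, 0], t[:, 0, 1]
            x1, y1 = t[:, 1, 0], t[:, 1, 1]
            x2, y2 = t[:, 2, 0], t[:, 2, 1]
            det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
            ok = np.abs(det) > 1e-14
            with np.errstate(divide="ignore", invalid="ignore"):
                l0 = ((y1 - y2) * (qx - x2) + (x2 - x1) * (qy - y2)) / det
                l1 = ((y2 - y0) * (qx - x2) + (x0 - x2) * (qy - y2)) / det
                l2 = 1.0 - l0 - l1
            hit = ok & (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
            if not np.any(hit):
                continue
            zhit = (
                l0[hit] * t[hit, 0, 2]
                + l1[hit] * t[hit, 1, 2]
                + l2[hit] * t[hit, 2, 2]
            )
            cols.append(
                px[inside_bbox][hit] * ny + py[inside_bbox][hit]
            )
            zs.append(zhit)

    out = np.zeros(grid.shape, dtype=np.uint8)
    if cols:
        col = np.concatenate(cols)
        z = np.concatenate(zs)
        order = np.lexsort((z, col))
        col, z = col[order], z[order]
        # alternate +1/-1 within each column (parity fill)
        start = np.r_[True, col[1:] != col[:-1]]
        run_pos = np.arange(len(col)) - np.maximum.accumulate(
            np.where(start, np.arange(len(col)), 0)
        )
        sign = np.where(run_pos % 2 == 0, 1, -1)
        # crossing at z affects voxel centers k >= z; clip into the grid
        # (entries clipped to 0 still open, exits past the top never close)
        k = np.clip(np.ceil(z).astype(np.int64), 0, nz)
        delta = np.zeros((nx * ny, nz + 1), dtype=np.int32)
        np.add.at(delta, (col, k), sign)
        inside = np.cumsum(delta[:, :nz], axis=1) > 0
        out = inside.reshape(nx, ny, nz).astype(np.uint8)
    return Volume(out, grid.affine, space_tag=grid.space_tag)


def contains_points(s: Surface, pts: np.ndarray) -> np.ndarray:
    """Inside test for a set of world-mm points (ray-crossing parity)."""
    return _trimath.points_in_mesh(pts, s.vertices, s.faces)


def nearest_point_on_surface(p: np.ndarray, s: Surface):
    """Closest point on any triangle of the mesh, with the outward unit
    normal of the containing triangle (faces are wound outward)."""
    if len(s.vertices) == 0:
        raise ValueError("empty surface")
    point, _, face = _trimath.nearest_on_mesh(np.asarray(p, float), s.vertices, s.faces)
    normal = _trimath.face_normals(s.vertices, s.faces[face : face + 1])[0]
    return point, normal
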