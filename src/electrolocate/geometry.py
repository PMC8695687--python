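"""Electrode position correction.

Surface (ECoG) contacts detected below the pial surface after
postsurgical brain shift are pushed back out onto the smoothed
projection surface — along the local grid normal for grids, to the
nearest surface point for strips, or along one of three user-selectable
vectors.  Depth (SEEG) contacts are straightened and re-spaced to the
manufacturer lead geometry, walking outward from the (trusted) deepest
contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrodes import Electrode, ElectrodeSet
from .surfaces import Surface, nearest_point_on_surface
from .volumes import RigidTransform


@dataclass
class LeadSpec:
    """Known depth-lead geometry; contacts ordered deepest -> superficial.

    ``gap_spacings_mm`` has one entry per inter-contact gap and supports
    grouped leads (e.g. 3.5 mm within 5-contact groups, 7 mm between
    groups)."""

    name: str
    n_contacts: int
    gap_spacings_mm: list

    def __post_init__(self) -> None:
        self.gap_spacings_mm = [float(g) for g in self.gap_spacings_mm]
        if self.n_contacts < 2:
            raise ValueError("a lead needs at least 2 contacts")
        if len(self.gap_spacings_mm) != self.n_contacts - 1:
            raise ValueError(
                f"expected {self.n_contacts - 1} gap spacings, "
                f"got {len(self.gap_spacings_mm)}"
            )
        if any(g <= 0 for g in self.gap_spacings_mm):
            raise ValueError("spacings must be positive")

    @staticmethod
    def regular(name: str, n_contacts: int, spacing_mm: float) -> "LeadSpec":
        return LeadSpec(name, n_contacts, [spacing_mm] * (n_contacts - 1))


@dataclass
class GridSpec:
    """Planar ECoG grid/strip: rows x cols at a uniform pitch."""

    rows: int
    cols: int
    pitch_mm: float

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise ValueError("grid must have at least one contact")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")

    @property
    def is_strip(self) -> bool:
        return self.rows == 1 or self.cols == 1


@dataclass
class ProjectionMode:
    """One of the three manual projection vector choices: from the brain
    center (mid-commissural point) through the contact, along the current
    view direction, or along the local projection-surface normal."""

    mode: str  # brain_center | view_direction | surface_normal
    view_dir: np.ndarray | None = None
    mcp_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("brain_center", "view_direction", "surface_normal"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if self.mode == "view_direction":
            if self.view_dir is None:
                raise ValueError("view_direction mode requires view_dir")
            self.view_dir = _unit(np.asarray(self.view_dir, float))
        elif self.view_dir is not None:
            raise ValueError("view_dir only valid in view_direction mode")
        if self.mode == "brain_center":
            if self.mcp_mm is None:
                raise ValueError("brain_center mode requires mcp_mm")
            self.mcp_mm = np.asarray(self.mcp_mm, float)
        elif self.mcp_mm is not None:
            raise ValueError("mcp_mm only valid in brain_center mode")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


# ---------------------------------------------------------------------------
# Ray casting


def ray_surface_intersection(origin, direction, s: Surface):
    """First intersection (smallest positive t) of the ray with the mesh,
    or None if the ray misses."""
    from . import _trimath

    tri = _trimath.triangles(s.vertices, s.faces)
    ts = _trimath.ray_hits(origin, direction, tri)
    if len(ts) == 0:
        return None
    return np.asarray(origin, float) + ts[0] * np.asarray(direction, float)


# ---------------------------------------------------------------------------
# ECoG projection


def _grid_positions_matrix(electrodes: ElectrodeSet, grid: GridSpec) -> np.ndarray:
    if len(electrodes) != grid.rows * grid.cols:
        raise ValueError(
            "grid topology unresolved: "
            f"{len(electrodes)} electrodes for a {grid.rows}x{grid.cols} grid"
        )
    return electrodes.positions.reshape(grid.rows, grid.cols, 3)


def _local_grid_normal(pos: np.ndarray, r: int, c: int) -> np.ndarray:
    """Normal from one-sided/central differences of grid neighbours."""
    rows, cols = pos.shape[:2]

    def diff(axis, k, lo, hi):
        if 0 < k < hi - 1:
            return pos[(k + 1, c) if axis == 0 else (r, k + 1)] - (
                pos[(k - 1, c) if axis == 0 else (r, k - 1)]
            )
        if k == 0:
            return pos[(1, c) if axis == 0 else (r, 1)] - pos[(0, c) if axis == 0 else (r, 0)]
        return pos[(k, c) if axis == 0 else (r, k)] - (
            pos[(k - 1, c) if axis == 0 else (r, k - 1)]
        )

    row_dir = diff(0, r, 0, rows)
    col_dir = diff(1, c, 0, cols)
    return _unit(np.cross(row_dir, col_dir))


def project_grid(
    electrodes: ElectrodeSet, grid: GridSpec, projection: Surface
) -> ElectrodeSet:
    """Brain-shift correction for a grid or strip.

    Grid contacts move along the local grid normal (estimated from
    labelled neighbours) to the nearer ray-surface intersection; strip
    contacts move to their nearest surface point.  Electrodes must be
    ordered row-major to match the grid spec.  Each returned electrode
    retains its pre-projection position in ``original_mm``.
    """
    import copy

    out = []
    if grid.is_strip:
        for e in electrodes:
            ne = copy.deepcopy(e)
            target, _ = nearest_point_on_surface(e.centroid_mm, projection)
            ne.original_mm = e.centroid_mm.copy()
            ne.centroid_mm = np.asarray(target, dtype=float)
            out.append(ne)
        return ElectrodeSet(out)

    pos = _grid_positions_matrix(electrodes, grid)
    for i, e in enumerate(electrodes):
        r, c = divmod(i, grid.cols)
        ne = copy.deepcopy(e)
        ne.original_mm = e.centroid_mm.copy()
        target, _ = nearest_point_on_surface(e.centroid_mm, projection)
        if np.linalg.norm(target - e.centroid_mm) < 1e-6:
            out.append(ne)  # already on the surface
            continue
        normal = _local_grid_normal(pos, r, c)
        hit_f = ray_surface_intersection(e.centroid_mm, normal, projection)
        hit_b = ray_surface_intersection(e.centroid_mm, -normal, projection)
        cands = [h for h in (hit_f, hit_b) if h is not None]
        if cands:
            dists = [np.linalg.norm(h - e.centroid_mm) for h in cands]
            ne.centroid_mm = cands[int(np.argmin(dists))]
        else:
            # ray misses the surface entirely: fall back to nearest point
            target, _ = nearest_point_on_surface(e.centroid_mm, projection)
            ne.centroid_mm = np.asarray(target, dtype=float)
        out.append(ne)
    return ElectrodeSet(out)


def projection_vector(
    e: Electrode, mode: ProjectionMode, projection: Surface | None = None
) -> np.ndarray:
    """Unit projection vector for one contact under the chosen mode."""
    if mode.mode == "brain_center":
        d = e.centroid_mm - mode.mcp_mm
        if np.linalg.norm(d) == 0:
            raise ValueError("undefined direction: electrode coincides with mcp")
        return _unit(d)
    if mode.mode == "view_direction":
        return mode.view_dir
    if projection is None:
        raise ValueError("surface_normal mode requires the projection surface")
    _, normal = nearest_point_on_surface(e.centroid_mm, projection)
    return normal


def project_along(
    e: Electrode, v: np.ndarray, projection: Surface, step_mm: float | None = None
) -> Electrode:
    """Move a contact along ``v``: to the first ray-surface intersection,
    or by exactly ``step_mm`` (nudge; no surface constraint) if given."""
    import copy

    v = _unit(np.asarray(v, dtype=float))
    ne = copy.deepcopy(e)
    if step_mm is not None:
        ne.centroid_mm = e.centroid_mm + step_mm * v
        return ne
    hit = ray_surface_intersection(e.centroid_mm, v, projection)
    if hit is None:
        raise ValueError("ray misses surface")
    ne.centroid_mm = hit
    return ne


# ---------------------------------------------------------------------------
# SEEG spacing correction


def correct_lead_spacing(contacts: np.ndarray, spec: LeadSpec) -> np.ndarray:
    """Re-space depth-lead contacts to the nominal lead geometry.

    The deepest contact (index 0) is trusted and fixed.  Each further
    contact k is placed at the nominal spacing from the corrected contact
    k-1 along the normalized mean of the vectors from corrected k-1 to
    the *original* contacts k and k+1 (only k for the last contact).
    Every corrected gap equals its nominal spacing exactly.
    """
    contacts = np.asarray(contacts, dtype=float)
    if contacts.shape != (spec.n_contacts, 3):
        raise ValueError(
            f"expected {spec.n_contacts} contact positions, got {contacts.shape}"
        )
    out = contacts.copy()
    n = spec.n_contacts
    for k in range(1, n):
        vecs = [contacts[k] - out[k - 1]]
        if k + 1 < n:
            vecs.append(contacts[k + 1] - out[k - 1])
        mean_vec = np.mean(vecs, axis=0)
        norm = np.linalg.norm(mean_vec)
        if norm < 1e-12:
            raise ValueError("degenerate lead geometry: zero direction vector")
        out[k] = out[k - 1] + spec.gap_spacings_mm[k - 1] * mean_vec / norm
    return out


# ---------------------------------------------------------------------------
# Inline projection


def inline_rotation(first, last, plane_normal) -> RigidTransform:
    """Minimal rotation (about the lead midpoint) bringing the lead
    vector into the viewing plane (lead . plane_normal = 0).

    For a lead parallel to the plane normal the rotation is by 90 degrees
    about a deterministic perpendicular axis (the least-aligned world
    axis crossed with the lead).
    """
    first = np.asarray(first, dtype=float)
    last = np.asarray(last, dtype=float)
    if np.allclose(first, last):
        raise ValueError("first and last contact coincide")
    u = _unit(last - first)
    nrm = _unit(np.asarray(plane_normal, dtype=float))
    axis = np.cross(u, nrm)
    sin_cross = np.linalg.norm(axis)
    if sin_cross < 1e-12:
        # lead parallel to the plane normal: any perpendicular axis works
        e = np.eye(3)[int(np.argmin(np.abs(u)))]
        axis = _unit(np.cross(u, e))
        angle = np.pi / 2.0
    else:
        axis = axis / sin_cross
        # rotate u within the u-n plane until u . n = 0
        angle = -np.arctan2(float(u @ nrm), sin_cross)
    rot = _rodrigues(axis, angle)
    mid = 0.5 * (first + last)
    return RigidTransform(rot, mid - rot @ mid)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
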