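"""Vectorized triangle-mesh queries: closest point, ray casting,
point-in-mesh parity tests.

Self-contained numpy implementations so the geometric core has no
optional spatial-index dependencies.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

_JITTER = np.array([3.7e-7, 2.3e-7, 0.0])  # breaks exact edge/vertex ray hits


def triangles(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    return vertices[faces]


def closest_points_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle (Ericson's region test,
    vectorized over triangles)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    settle((d3 >= 0) & (d4 <= d3), b)

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    settle((d6 >= 0) & (d5 <= d6), c)

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc[:, None] * (c - b))

    total = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(total != 0, 1.0 / total, 0.0)
    interior = a + (vb * inv)[:, None] * ab + (vc * inv)[:, None] * ac
    settle(np.ones(len(tri), dtype=bool), interior)
    return out


def nearest_on_mesh(p: np.ndarray, vertices: np.ndarray, faces: np.ndarray):
    """(closest point, distance, face index) over the whole mesh."""
    tri = triangles(vertices, faces)
    cand = closest_points_on_triangles(np.asarray(p, dtype=float), tri)
    d = np.linalg.norm(cand - p, axis=1)
    i = int(np.argmin(d))
    return cand[i], float(d[i]), i


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = triangles(vertices, faces)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1)
    norm[norm == 0] = 1.0
    return n / norm[:, None]


def ray_hits(origin, direction, tri, eps: float = 1e-9):
    """Moller-Trumbore over all triangles: sorted positive ray
    parameters t (may be empty)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    h = np.cross(np.broadcast_to(direction, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(ok, 1.0 / det, 0.0)
        s = origin - v0
        u = inv * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = inv * (q @ direction)
        t = inv * np.einsum("ij,ij->i", e2, q)
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > eps)
    return np.sort(t[hit])


class _FaceBuckets:
    """2-D (x, y) hash grid over triangle bounding boxes, for cheap
    candidate lookup of the triangles a vertical ray can cross."""

    def __init__(self, tri: np.ndarray):
        self.tri = tri
        spans = tri.max(axis=1) - tri.min(axis=1)
        self.cell = float(max(np.median(spans[:, :2]) * 2.0, 1e-6))
        lo = np.floor(tri[:, :, :2].min(axis=1) / self.cell).astype(np.int64)
        hi = np.floor(tri[:, :, :2].max(axis=1) / self.cell).astype(np.int64)
        buckets = defaultdict(list)
        for f in range(len(tri)):
            for cx in range(lo[f, 0], hi[f, 0] + 1):
                for cy in range(lo[f, 1], hi[f, 1] + 1):
                    buckets[(cx, cy)].append(f)
        self.buckets = {k: np.array(v, dtype=np.int64) for k, v in buckets.items()}

    def candidates(self, x: float, y: float) -> np.ndarray:
        key = (int(np.floor(x / self.cell)), int(np.floor(y / self.cell)))
        return self.buckets.get(key, np.empty(0, dtype=np.int64))


def points_in_mesh(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Inside test by parity of upward (+z) ray crossings."""
    tri = triangles(vertices, faces)
    index = _FaceBuckets(tri)
    pts = np.atleast_2d(np.asarray(points, dtype=float)) + _JITTER
    out = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        cand = index.candidates(p[0], p[1])
        if len(cand) == 0:
            continue
        t = tri[cand]
        # 2-D point-in-triangle in the xy projection, then z crossing
        x0, y0 = t[:, 0, 0], t[:, 0, 1]
        x1, y1 = t[:, 1, 0], t[:, 1, 1]
        x2, y2 = t[:, 2, 0], t[:, 2, 1]
        det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        ok = np.abs(det) > 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            l0 = ((y1 - y2) * (p[0] - x2) + (x2 - x1) * (p[1] - y2)) / det
            l1 = ((y2 - y0) * (p[0] - x2) + (x0 - x2) * (p[1] - y2)) / det
            l2 = 1.0 - l0 - l1
        hit = ok & (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not np.any(hit):
            continue
        z = l0[hit] * t[hit, 0, 2] + l1[hit] * t[hit, 1, 2] + l2[hit] * t[hit, 2, 2]
        out[i] = int(np.sum(z > p[2])) % 2 == 1
    return out
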