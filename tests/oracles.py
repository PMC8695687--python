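"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths (and, where practical, the
libraries) used by the package itself.
"""

import itertools

import numpy as np


def closest_point_on_triangle(p, a, b, c):
    """Ericson's algorithm, scalar form."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def brute_force_nearest(p, vertices, faces):
    """Exhaustive closest point over every triangle."""
    best, best_d = None, np.inf
    for f in faces:
        q = closest_point_on_triangle(
            np.asarray(p, float), vertices[f[0]], vertices[f[1]], vertices[f[2]]
        )
        d = np.linalg.norm(q - p)
        if d < best_d:
            best, best_d = q, d
    return best, best_d


def moller_trumbore(origin, direction, vertices, faces, eps=1e-9):
    """Smallest positive ray parameter over all triangles, or None."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    best_t = np.inf
    for f in faces:
        v0, v1, v2 = vertices[f[0]], vertices[f[1]], vertices[f[2]]
        e1, e2 = v1 - v0, v2 - v0
        h = np.cross(direction, e2)
        a = e1 @ h
        if abs(a) < 1e-12:
            continue
        inv = 1.0 / a
        s = origin - v0
        u = inv * (s @ h)
        if u < -1e-12 or u > 1 + 1e-12:
            continue
        q = np.cross(s, e1)
        v = inv * (direction @ q)
        if v < -1e-12 or u + v > 1 + 1e-12:
            continue
        t = inv * (e2 @ q)
        if t > eps and t < best_t:
            best_t = t
    if np.isinf(best_t):
        return None
    return origin + best_t * direction


def mesh_volume_signed_tetrahedra(vertices, faces):
    """Enclosed volume via the divergence theorem over signed tetrahedra."""
    v = vertices[faces]
    return abs(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


def exact_ranksum_pvalue(x, y):
    """Two-sided rank-sum p by full enumeration of C(n+m, n) splits."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:nx].sum()
    mu = nx * (nx + len(y) + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def brute_force_optimal_index(counts, delta):
    """Stable-segment threshold choice, re-derived step by step:
    split the curve wherever consecutive counts jump by more than delta,
    score each maximal run by its peak count (ties: longer run, then
    lower threshold), and return the run's center index (lower-middle)."""
    counts = list(counts)
    runs = []
    start = 0
    for i in range(1, len(counts)):
        if abs(counts[i] - counts[i - 1]) > delta:
            runs.append(list(range(start, i)))
            start = i
    runs.append(list(range(start, len(counts))))
    best = None
    for run in runs:
        score = (max(counts[i] for i in run), len(run), -run[0])
        if best is None or score > best[0]:
            best = (score, run)
    run = best[1]
    return run[(len(run) - 1) // 2] if len(run) % 2 == 0 else run[len(run) // 2]


def trilinear_sample(data, affine, points_mm, fill=0.0):
    """Hand-rolled trilinear interpolation at world points."""
    inv = np.linalg.inv(affine)
    out = []
    for p in np.atleast_2d(points_mm):
        idx = inv[:3, :3] @ p + inv[:3, 3]
        i0 = np.floor(idx).astype(int)
        f = idx - i0
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    j = i0 + [dx, dy, dz]
                    if np.any(j < 0) or np.any(j >= np.array(data.shape)):
                        val = fill
                    else:
                        val = data[tuple(j)]
                    w = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    acc += w * val
        out.append(acc)
    return np.array(out)


def hungarian_match(detected, truth):
    """Optimal one-to-one matching distances between two point sets."""
    from scipy.optimize import linear_sum_assignment

    D = np.linalg.norm(
        np.asarray(detected)[:, None, :] - np.asarray(truth)[None, :, :], axis=2
    )
    r, c = linear_sum_assignment(D)
    return D[r, c], r, c
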