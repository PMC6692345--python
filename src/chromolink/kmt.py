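"""Koniaris-Muthukumar-Taylor chain simplification, obstacle-aware.

An interior vertex v with neighbours u, w is removed when the triangle
(u, v, w) is intersected by no other segment — of the chain itself or of any
obstacle chain.  Removing such a vertex is an isotopy, so the reduced chain
has the same knot/link type and the same GLN against every obstacle.  For
link analysis the obstacle check is essential: without it a triangle move
could pass one chromosome through another and silently change the link.

Sweeps run in ascending vertex order and restart until a full pass removes
nothing, giving deterministic output.  The intersection test treats the
closed triangle conservatively (boundary contact counts, epsilon 1e-9 nm):
a vertex is kept whenever removal might be unsafe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_io import Polyline

__all__ = ["ReductionResult", "kmt", "triangle_segment_intersects"]

_EPS = 1e-9
_DEGENERATE_AREA = 1e-12


@dataclass
class ReductionResult:
    chain: Polyline
    removed_count: int
    kept_original_indices: list[int]


def triangle_segment_intersects(tri: np.ndarray, p0: np.ndarray,
                                p1: np.ndarray, eps: float = _EPS) -> bool:
    """Conservative closed-triangle vs segment intersection test."""
    res = _tri_seg_many(tri, p0[None, :], p1[None, :], eps)
    return bool(res[0])


def _tri_seg_many(tri: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                  eps: float = _EPS) -> np.ndarray:
    """Vectorized: does each segment (p0[k], p1[k]) touch triangle ``tri``?"""
    a, b, c = tri
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < _DEGENERATE_AREA:
        # degenerate triangle: fall back to distance-to-segment-uvw checks;
        # callers treat the vertex as collinear and removable
        return np.zeros(len(p0), dtype=bool)
    n = n / nn
    d0 = (p0 - a) @ n
    d1 = (p1 - a) @ n
    out = np.zeros(len(p0), dtype=bool)

    # segments clearly on one side cannot intersect
    same_side = (np.minimum(np.abs(d0), np.abs(d1)) > eps) & (d0 * d1 > 0)
    todo = ~same_side
    if not np.any(todo):
        return out

    # basis in the triangle plane for 2D tests
    e1 = b - a
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    tri2 = np.array([[0.0, 0.0],
                     [(b - a) @ e1, (b - a) @ e2],
                     [(c - a) @ e1, (c - a) @ e2]])

    idx = np.flatnonzero(todo)
    for k in idx:
        out[k] = _tri_seg_single(tri2, n, a, e1, e2,
                                 p0[k], p1[k], d0[k], d1[k], eps)
    return out


def _point_in_tri2(tri2: np.ndarray, q: np.ndarray, eps: float) -> bool:
    v0, v1, v2 = tri2
    d = (v1[0] - v0[0]) * (v2[1] - v0[1]) - (v2[0] - v0[0]) * (v1[1] - v0[1])
    w1 = ((q[0] - v0[0]) * (v2[1] - v0[1]) - (v2[0] - v0[0]) * (q[1] - v0[1])) / d
    w2 = ((v1[0] - v0[0]) * (q[1] - v0[1]) - (q[0] - v0[0]) * (v1[1] - v0[1])) / d
    return w1 >= -eps and w2 >= -eps and (w1 + w2) <= 1 + eps


def _seg2_intersect(a0, a1, b0, b1, eps) -> bool:
    u = a1 - a0
    w = b1 - b0
    denom = u[0] * w[1] - u[1] * w[0]
    r = b0 - a0
    if abs(denom) < 1e-14:
        # parallel: touching only if collinear and overlapping
        if abs(r[0] * u[1] - r[1] * u[0]) > eps * (np.hypot(*u) + 1e-30):
            return False
        lu2 = u @ u
        if lu2 < 1e-30:
            return np.hypot(*(b0 - a0)) <= eps
        t0 = (r @ u) / lu2
        t1 = ((b1 - a0) @ u) / lu2
        lo, hi = min(t0, t1), max(t0, t1)
        return hi >= -eps and lo <= 1 + eps
    t = (r[0] * w[1] - r[1] * w[0]) / denom
    s = (r[0] * u[1] - r[1] * u[0]) / denom
    return -eps <= t <= 1 + eps and -eps <= s <= 1 + eps


def _tri_seg_single(tri2, n, a, e1, e2, p0, p1, d0, d1, eps) -> bool:
    both_near = abs(d0) <= eps and abs(d1) <= eps
    if both_near:
        # coplanar: 2D segment vs triangle
        q0 = np.array([(p0 - a) @ e1, (p0 - a) @ e2])
        q1 = np.array([(p1 - a) @ e1, (p1 - a) @ e2])
        if _point_in_tri2(tri2, q0, eps) or _point_in_tri2(tri2, q1, eps):
            return True
        edges = [(tri2[0], tri2[1]), (tri2[1], tri2[2]), (tri2[2], tri2[0])]
        return any(_seg2_intersect(q0, q1, ea, eb, eps) for ea, eb in edges)
    denom = d0 - d1
    if abs(denom) < 1e-30:
        return False
    s = d0 / denom
    if s < -eps or s > 1 + eps:
        return False
    x = p0 + np.clip(s, 0.0, 1.0) * (p1 - p0)
    q = np.array([(x - a) @ e1, (x - a) @ e2])
    return _point_in_tri2(tri2, q, eps)


def _segment_arrays(chain_vertices: np.ndarray, closed: bool):
    if closed:
        return chain_vertices, np.roll(chain_vertices, -1, axis=0)
    return chain_vertices[:-1], chain_vertices[1:]


def kmt(chain: Polyline, obstacles: list[Polyline] | None = None,
        min_vertices: int = 3) -> ReductionResult:
    """Reduce a chain without changing its entanglement with obstacles.

    Open chains keep their endpoints; closed chains are never reduced below
    ``min_vertices``.  ``obstacles`` are the other chains of the link system.
    """
    obstacles = obstacles or []
    obs_segments = [_segment_arrays(o.vertices, o.closed) for o in obstacles]

    verts = list(chain.vertices)
    kept = list(range(len(verts)))
    removed = 0
    changed = True
    while changed:
        changed = False
        i = 1 if not chain.closed else 0
        while True:
            nv = len(verts)
            limit = nv - 1 if not chain.closed else nv
            if i >= limit or nv <= (min_vertices if chain.closed else 2):
                break
            u_i = (i - 1) % nv
            w_i = (i + 1) % nv
            tri = np.array([verts[u_i], verts[i], verts[w_i]])
            if _removable(tri, verts, chain.closed, u_i, i, w_i, obs_segments):
                del verts[i]
                del kept[i]
                removed += 1
                changed = True
                # stay at the same index (next vertex shifted into place)
            else:
                i += 1
    reduced = Polyline(np.asarray(verts), closed=chain.closed)
    return ReductionResult(chain=reduced, removed_count=removed,
                           kept_original_indices=kept)


_TRIM = 1e-4  # fraction trimmed off a neighbour segment at its shared vertex


def _removable(tri, verts, closed, u_i, v_i, w_i, obs_segments) -> bool:
    area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area2 < _DEGENERATE_AREA:
        return True  # collinear vertex
    p0s, p1s = _segment_arrays(np.asarray(verts), closed)
    p0s, p1s = p0s.copy(), p1s.copy()
    nseg = len(p0s)
    mask = np.ones(nseg, dtype=bool)
    # the triangle's own edges (u,v) and (v,w) are never tested
    mask[u_i % nseg] = False
    mask[v_i % nseg] = False
    # segments sharing only u or w always touch the closed triangle at that
    # vertex; trim the shared endpoint so only genuine piercing counts
    before = (u_i - 1) % nseg if closed else u_i - 1
    after = w_i % nseg if closed else w_i
    if 0 <= before < nseg and mask[before]:
        p1s[before] = p0s[before] + (1 - _TRIM) * (p1s[before] - p0s[before])
    if 0 <= after < nseg and mask[after]:
        p0s[after] = p0s[after] + _TRIM * (p1s[after] - p0s[after])
    if np.any(mask):
        if np.any(_tri_seg_many(tri, p0s[mask], p1s[mask])):
            return False
    for o0, o1 in obs_segments:
        if np.any(_tri_seg_many(tri, o0, o1)):
            return False
    return True
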