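"""Generic projection of closed 3D polylines to a crossing diagram."""

from __future__ import annotations

import numpy as np

from ..chain_io import Polyline
from .diagram import Diagram, NonGenericProjection

__all__ = ["project_diagram", "random_direction"]

_PARAM_EPS = 1e-9


def random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)  # (e1, e2, d) right-handed
    return e1, e2, d


def project_diagram(chains: list[Polyline], direction: np.ndarray) -> Diagram:
    """Project closed chains along ``direction`` and extract the diagram.

    Every pairwise segment crossing in the projection plane is recorded with
    over/under read off the depth along ``direction`` (the over strand is the
    one nearer the viewer at +direction) and sign by the right-hand rule.

    Raises
    ------
    NonGenericProjection
        when two segments are near-parallel at a crossing, a crossing sits
        too close to a vertex, two crossings coincide, or the two strands
        have nearly equal depth; the caller should resample the direction.
    """
    for ch in chains:
        if not ch.closed:
            raise ValueError("project_diagram requires closed chains")
    e1, e2, d = _basis(direction)

    pts2: list[np.ndarray] = []
    depth: list[np.ndarray] = []
    scale = 0.0
    for ch in chains:
        v = ch.vertices
        pts2.append(np.c_[v @ e1, v @ e2])
        depth.append(v @ d)
        ext = v.max(axis=0) - v.min(axis=0)
        scale = max(scale, float(np.max(ext)))
    scale = scale or 1.0

    # crossing records: (chain, seg, t, partner info ...)
    crossings = []  # (cid, chain, seg, t, role, sign)
    cid = 0
    n_chains = len(chains)
    for ca in range(n_chains):
        na = len(pts2[ca])
        for cb in range(ca, n_chains):
            nb = len(pts2[cb])
            for ia in range(na):
                a0 = pts2[ca][ia]
                a1 = pts2[ca][(ia + 1) % na]
                u = a1 - a0
                jb_range = range(ia + 1, nb) if ca == cb else range(nb)
                for ib in jb_range:
                    if ca == cb:
                        # skip identical and cyclically adjacent segments
                        if ib == ia or (ib + 1) % na == ia or (ia + 1) % na == ib:
                            continue
                    b0 = pts2[cb][ib]
                    b1 = pts2[cb][(ib + 1) % nb]
                    w = b1 - b0
                    denom = u[0] * w[1] - u[1] * w[0]
                    lu = np.hypot(*u)
                    lw = np.hypot(*w)
                    if abs(denom) <= 1e-12 * lu * lw:
                        # parallel in projection: only a problem if they overlap
                        if _boxes_touch(a0, a1, b0, b1):
                            raise NonGenericProjection("near-parallel segments")
                        continue
                    r = b0 - a0
                    t = (r[0] * w[1] - r[1] * w[0]) / denom
                    s = (r[0] * u[1] - r[1] * u[0]) / denom
                    if -_PARAM_EPS < t < _PARAM_EPS or 1 - _PARAM_EPS < t < 1 + _PARAM_EPS:
                        if -1e-4 < s < 1 + 1e-4:
                            raise NonGenericProjection("crossing at a vertex")
                    if -_PARAM_EPS < s < _PARAM_EPS or 1 - _PARAM_EPS < s < 1 + _PARAM_EPS:
                        if -1e-4 < t < 1 + 1e-4:
                            raise NonGenericProjection("crossing at a vertex")
                    if not (0 < t < 1 and 0 < s < 1):
                        continue
                    ha = depth[ca][ia] + t * (depth[ca][(ia + 1) % na] - depth[ca][ia])
                    hb = depth[cb][ib] + s * (depth[cb][(ib + 1) % nb] - depth[cb][ib])
                    if abs(ha - hb) <= 1e-9 * scale:
                        raise NonGenericProjection("ambiguous depth at crossing")
                    over_a = ha > hb
                    du_over, du_under = (u, w) if over_a else (w, u)
                    # right-hand rule: positive when the over direction,
                    # rotated CCW (viewed from +direction), meets the under
                    cr = du_over[0] * du_under[1] - du_over[1] * du_under[0]
                    sign = 1 if cr > 0 else -1
                    crossings.append((cid, ca, ia, t, "o" if over_a else "u", sign))
                    crossings.append((cid, cb, ib, s, "u" if over_a else "o", sign))
                    cid += 1

    # order passes along each chain; reject coincident crossing positions
    comps = []
    for c in range(n_chains):
        passes = [rec for rec in crossings if rec[1] == c]
        passes.sort(key=lambda rec: (rec[2], rec[3]))
        for p, q in zip(passes, passes[1:]):
            if p[2] == q[2] and abs(p[3] - q[3]) < _PARAM_EPS:
                raise NonGenericProjection("coincident crossings on a segment")
        comps.append(tuple((rec[0], rec[4], rec[5]) for rec in passes))
    diagram = Diagram(tuple(comps))
    diagram.validate()
    return diagram


def _boxes_touch(a0, a1, b0, b1) -> bool:
    alo = np.minimum(a0, a1) - 1e-12
    ahi = np.maximum(a0, a1) + 1e-12
    blo = np.minimum(b0, b1) - 1e-12
    bhi = np.maximum(b0, b1) + 1e-12
    return bool(np.all(alo <= bhi) and np.all(blo <= ahi))
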