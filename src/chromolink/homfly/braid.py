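"""Geometric 3D realizations of braid closures.

A braid word (1-based Artin generators, sign = crossing handedness) is
embedded as piecewise-linear strands in 3D: strands run along +y at integer
x positions with z = 0, each letter swaps two neighbouring strands along
crossing diagonals lifted to z = +-1/2, and the closure arcs are nested
rectangles to the side of the braid.  Projecting along +z therefore yields a
diagram with exactly one crossing per letter, which makes these curves
trustworthy canonical inputs for the classification-table builder.
"""

from __future__ import annotations

import numpy as np

from ..chain_io import Polyline

__all__ = ["braid_curves"]


def braid_curves(word: list[int], n_strands: int | None = None,
                 over_moves_right: bool = True) -> list[Polyline]:
    """Closed 3D curves realizing the closure of a braid word.

    ``word`` uses nonzero integers: letter ``+i`` / ``-i`` crosses the
    strands at positions i-1 and i (0-based) with opposite handedness; which
    of the two strands passes over is controlled by ``over_moves_right``
    combined with the letter sign.
    """
    if not word or any(w == 0 for w in word):
        raise ValueError("braid word must be nonzero integers")
    n = n_strands or (max(abs(w) for w in word) + 1)
    if max(abs(w) for w in word) > n - 1:
        raise ValueError("generator index exceeds strand count")

    # strand paths: one vertex list per *starting position*
    paths: list[list[np.ndarray]] = [[np.array([float(p), 0.0, 0.0])]
                                     for p in range(n)]
    pos_to_strand = list(range(n))  # position -> strand index

    for j, w in enumerate(word):
        g = abs(w) - 1  # crosses positions g, g+1
        y0, y1 = float(j), float(j + 1)
        sL = pos_to_strand[g]
        sR = pos_to_strand[g + 1]
        right_over = (w > 0) == over_moves_right
        zL = -0.5 if right_over else 0.5   # strand moving right: g -> g+1
        zR = -zL
        for s, xa, xb, z in ((sL, g, g + 1, zL), (sR, g + 1, g, zR)):
            if paths[s][-1][1] < y0:  # bring the strand down to the letter row
                paths[s].append(np.array([float(xa), y0, 0.0]))
            xm1 = xa + 0.25 * (xb - xa)
            xm2 = xa + 0.75 * (xb - xa)
            paths[s].append(np.array([xm1, y0 + 0.25, z]))
            paths[s].append(np.array([xm2, y0 + 0.75, z]))
            paths[s].append(np.array([float(xb), y1, 0.0]))
        pos_to_strand[g], pos_to_strand[g + 1] = sR, sL

    M = float(len(word))
    end_pos = {pos_to_strand[p]: p for p in range(n)}

    # permutation: strand s starts at position s and ends at position end_pos[s]
    curves = []
    visited = [False] * n
    for start in range(n):
        if visited[start]:
            continue
        verts: list[np.ndarray] = []
        s = start
        while not visited[s]:
            visited[s] = True
            path = paths[s]
            if path[-1][1] < M:  # strand untouched by any letter after its last vertex
                path = path + [np.array([path[-1][0], M, 0.0])]
            verts.extend(path)
            q = end_pos[s]  # top position; closure arc q -> bottom position q
            rank = n - q  # rightmost position gets the innermost arc
            x_arc = (n - 1) + 0.7 * rank
            y_top = M + 0.7 * rank
            y_bot = -0.7 * rank
            verts.append(np.array([float(q), y_top, 0.0]))
            verts.append(np.array([x_arc, y_top, 0.0]))
            verts.append(np.array([x_arc, y_bot, 0.0]))
            verts.append(np.array([float(q), y_bot, 0.0]))
            s = q  # continue from bottom position q
        # drop consecutive duplicates
        clean = [verts[0]]
        for v in verts[1:]:
            if np.linalg.norm(v - clean[-1]) > 1e-9:
                clean.append(v)
        if np.linalg.norm(clean[0] - clean[-1]) <= 1e-9:
            clean.pop()
        curves.append(Polyline(np.asarray(clean), closed=True))
    return curves
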