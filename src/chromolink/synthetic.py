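"""Parametric knots/links and toy genome ensembles.

Everything the analysis pipeline consumes can be generated here without any
external structure data: closed parametric curves of known topology (torus
knots/links, the figure-eight knot, the Whitehead link), opened variants
with endpoint gaps, tails and bead jitter, and confined random-walk "toy
genomes" with planted Hopf-linked pairs and known ground truth.

The Whitehead link is included deliberately: its Gauss linking number is 0,
so it is invisible to the |GLN| screen while still being a nontrivial link —
the stated blind spot of GLN-based detection, reproduced here as executable
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_io import Chromosome, GenomeModel, Polyline
from .homfly.braid import braid_curves

__all__ = ["SyntheticSpec", "make_link", "make_toy_genome",
           "torus_curve", "torus_link", "figure8_curve", "circle",
           "open_chain", "insert_local_knot", "hopf_pair", "threaded_pair",
           "whitehead_link", "jitter"]


# ---------------------------------------------------------------------------
# closed parametric curves


def circle(n_beads: int = 100, radius: float = 1.0,
           center=(0.0, 0.0, 0.0), normal: str = "z") -> Polyline:
    t = np.linspace(0.0, 2 * np.pi, n_beads, endpoint=False)
    flat = np.c_[np.cos(t), np.sin(t), np.zeros_like(t)] * radius
    axes = {"z": (0, 1, 2), "y": (2, 0, 1), "x": (1, 2, 0)}[normal]
    pts = flat[:, np.argsort(axes)]
    return Polyline(pts + np.asarray(center, dtype=float), closed=True)


def torus_curve(p: int, q: int, n_beads: int = 200, R: float = 3.0,
                r: float = 1.2) -> Polyline:
    """(p, q) torus knot, e.g. (2, 3) trefoil, (2, 5) 5_1, (2, 7) 7_1."""
    if np.gcd(p, q) != 1:
        raise ValueError("torus_curve needs coprime (p, q); use torus_link")
    t = np.linspace(0.0, 2 * np.pi, n_beads, endpoint=False)
    rad = R + r * np.cos(q * t)
    return Polyline(np.c_[rad * np.cos(p * t), rad * np.sin(p * t),
                          r * np.sin(q * t)], closed=True)


def torus_link(k: int, n_beads: int = 200, R: float = 3.0,
               r: float = 1.2) -> list[Polyline]:
    """The (2, 2k) torus link: Hopf (k=1), Solomon (k=2), 6^2_1 (k=3)...

    Two components winding k times around each other; |GLN| = k.
    """
    t = np.linspace(0.0, 2 * np.pi, n_beads, endpoint=False)
    out = []
    for phase in (0.0, np.pi):
        rad = R + r * np.cos(k * t + phase)
        out.append(Polyline(np.c_[rad * np.cos(t), rad * np.sin(t),
                                  r * np.sin(k * t + phase)], closed=True))
    return out


def hopf_pair(n_beads: int = 100, radius: float = 1.0,
              center=(0.0, 0.0, 0.0)) -> list[Polyline]:
    """Two interlocked perpendicular circles (the standard Hopf geometry)."""
    c = np.asarray(center, dtype=float)
    a = circle(n_beads, radius, center=c, normal="z")
    b = circle(n_beads, radius, center=c + [radius, 0.0, 0.0], normal="y")
    return [a, b]


def figure8_curve(n_beads: int = 240) -> Polyline:
    t = np.linspace(0.0, 2 * np.pi, n_beads, endpoint=False)
    rad = 2.0 + np.cos(2 * t)
    return Polyline(np.c_[rad * np.cos(3 * t), rad * np.sin(3 * t),
                          np.sin(4 * t)], closed=True)


def whitehead_link(scale: float = 1.0) -> list[Polyline]:
    """Whitehead link (GLN = 0, nontrivially linked), from its braid closure."""
    curves = braid_curves([1, -2, 1, -2, 1])
    return [Polyline(c.vertices * scale, closed=True) for c in curves]


def threaded_pair(turns: int = 3, helix_r: float = 1.2, pitch: float = 2.5,
                  rod_len: float = 30.0, spacing: float = 0.8,
                  tail: float = 6.0) -> list[Polyline]:
    """A deeply threaded open pair: a helix wound around a long chain.

    Chain A is a straight rod; chain B winds ``turns`` times around its
    middle, with radial tails leading away.  |GLN| is approximately the
    number of turns, and because unthreading requires sliding the whole
    helix off the rod end, the pair is stable on short relaxation timescales
    — the geometry of a deeply wound chromosome pair, reduced to its core.
    """
    nz = int(rod_len / spacing)
    rod = np.c_[np.zeros(nz), np.zeros(nz),
                np.linspace(-rod_len / 2, rod_len / 2, nz)]
    npts = int(turns * 2 * np.pi * helix_r / spacing)
    th = np.linspace(0.0, 2 * np.pi * turns, npts)
    z = np.linspace(-turns * pitch / 2, turns * pitch / 2, npts)
    H = np.c_[helix_r * np.cos(th), helix_r * np.sin(th), z]
    nt = int(tail / spacing)
    d0 = np.array([np.cos(th[0]), np.sin(th[0]), 0.0])
    d1 = np.array([np.cos(th[-1]), np.sin(th[-1]), 0.0])
    head = H[0] + d0 * spacing * np.arange(nt, 0, -1)[:, None]
    foot = H[-1] + d1 * spacing * np.arange(1, nt + 1)[:, None]
    return [Polyline(rod), Polyline(np.vstack([head, H, foot]))]


# ---------------------------------------------------------------------------
# opening, tails, noise


def open_chain(chain: Polyline, gap_fraction: float = 0.02,
               tails: float = 0.0, rng: np.random.Generator | None = None,
               noise_sd: float = 0.0) -> Polyline:
    """Open a closed curve by deleting a short arc, optionally adding tails.

    ``gap_fraction`` of the beads (at least 1) is removed around parameter 0;
    straight tails of the given length (same units as the curve) extend each
    new endpoint outward along its end-segment direction; Gaussian jitter of
    ``noise_sd`` is applied to every bead.
    """
    if not chain.closed:
        raise ValueError("open_chain expects a closed curve")
    v = chain.vertices
    n = len(v)
    n_gap = max(1, int(round(gap_fraction * n)))
    if n - n_gap < 2:
        raise ValueError("gap removes nearly the whole curve")
    pts = v[n_gap:]  # delete beads [0, n_gap)
    if tails > 0:
        step = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        n_tail = max(1, int(round(tails / step)))
        d0 = pts[0] - pts[1]
        d0 /= np.linalg.norm(d0)
        d1 = pts[-1] - pts[-2]
        d1 /= np.linalg.norm(d1)
        head = pts[0] + d0 * step * np.arange(n_tail, 0, -1)[:, None]
        tail = pts[-1] + d1 * step * np.arange(1, n_tail + 1)[:, None]
        pts = np.vstack([head, pts, tail])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return Polyline(pts, closed=False)


def jitter(chain: Polyline, noise_sd: float,
           rng: np.random.Generator) -> Polyline:
    return Polyline(chain.vertices + rng.normal(scale=noise_sd,
                                                size=chain.vertices.shape),
                    closed=chain.closed)


def insert_local_knot(chain: Polyline, at_vertex: int, kind: str = "trefoil",
                      size: float = 0.25) -> Polyline:
    """Splice a small local knot into one edge of a curve (connected sum).

    A scaled trefoil (or figure-eight) opened at a tiny gap is placed on the
    edge following ``at_vertex``; because the insert is local and small, the
    result is the connected sum of the original curve with that knot.
    """
    maker = {"trefoil": lambda: torus_curve(2, 3, n_beads=120),
             "figure8": lambda: figure8_curve(160)}[kind]()
    v = chain.vertices
    i = at_vertex % len(v)
    a = v[i]
    b = v[(i + 1) % len(v)] if chain.closed or i + 1 < len(v) else None
    if b is None:
        raise ValueError("at_vertex has no following edge")
    edge = b - a
    elen = np.linalg.norm(edge)
    k = maker.vertices
    # open the small knot at its largest gap-friendly point: drop one bead
    k = k[1:]
    k = k - k.mean(axis=0)
    k = k * (size * elen / np.max(np.linalg.norm(k, axis=1)))
    # align travel across the opened knot (first -> last bead) with the edge
    d = k[-1] - k[0]
    Rm = _rotation_between(d / np.linalg.norm(d), edge / elen)
    k = k @ Rm.T
    mid = a + 0.5 * edge
    k = k + (mid - 0.5 * (k[0] + k[-1]))
    new = np.vstack([v[: i + 1], k, v[i + 1:]])
    return Polyline(new, closed=chain.closed)


def _rotation_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector w."""
    c = float(u @ w)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = _skew(axis)
        return np.eye(3) + 2 * K @ K
    axis = np.cross(u, w)
    s = np.linalg.norm(axis)
    K = _skew(axis / s)
    ang = np.arctan2(s, c)
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K


def _skew(a: np.ndarray) -> np.ndarray:
    return np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])


# ---------------------------------------------------------------------------
# the SyntheticSpec front end

_KINDS = ("unknot", "trefoil", "figure8", "hopf", "solomon", "whitehead",
          "torus", "split_union", "connected_sum")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic knot or link.

    ``endpoint_gap`` = 0 keeps components closed; otherwise it is the bead
    fraction removed to open each component.  ``tails`` is the straight tail
    length appended at each new end.  ``torus_pq`` selects the torus family.
    """

    kind: str = "hopf"
    n_beads: int = 120
    endpoint_gap: float = 0.0
    tails: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    torus_pq: tuple[int, int] = (2, 3)
    sum_factors: tuple[str, str] = ("trefoil", "trefoil")

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_beads < 6:
            raise ValueError("need at least 6 beads per component")


def make_link(spec: SyntheticSpec) -> list[Polyline]:
    """Build the curves of a synthetic spec (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beads
    if spec.kind == "unknot":
        comps = [circle(n)]
    elif spec.kind == "trefoil":
        comps = [torus_curve(2, 3, n)]
    elif spec.kind == "figure8":
        comps = [figure8_curve(n)]
    elif spec.kind == "hopf":
        comps = hopf_pair(n)
    elif spec.kind == "solomon":
        comps = torus_link(2, n)
    elif spec.kind == "whitehead":
        comps = whitehead_link()
    elif spec.kind == "torus":
        p, q = spec.torus_pq
        if (p, q) == (2, 2) or (p == 2 and q % 2 == 0):
            comps = torus_link(q // 2, n)
        else:
            comps = [torus_curve(p, q, n)]
    elif spec.kind == "split_union":
        a = torus_curve(2, 3, n)
        b = Polyline(torus_curve(2, 3, n).vertices + np.array([12.0, 0, 0]),
                     closed=True)
        comps = [a, b]
    elif spec.kind == "connected_sum":
        base = {"trefoil": lambda: torus_curve(2, 3, n),
                "figure8": lambda: figure8_curve(n),
                "unknot": lambda: circle(n)}
        comps = [insert_local_knot(base[spec.sum_factors[0]](), 0,
                                   kind=spec.sum_factors[1], size=0.22)]
    out = []
    for c in comps:
        if spec.endpoint_gap > 0:
            c = open_chain(c, gap_fraction=spec.endpoint_gap,
                           tails=spec.tails, rng=rng, noise_sd=spec.noise_sd)
        elif spec.noise_sd > 0:
            c = jitter(c, spec.noise_sd, rng)
        out.append(c)
    _reject_self_intersections(out)
    return out


def _reject_self_intersections(chains: list[Polyline]) -> None:
    for ch in chains:
        steps = np.linalg.norm(np.diff(ch.vertices, axis=0), axis=1)
        if np.any(steps < 1e-6):
            raise ValueError("requested noise collapses adjacent beads; "
                             "reduce noise_sd or bead count")


# ---------------------------------------------------------------------------
# toy genomes


def make_toy_genome(n_chroms: int = 20, n_linked_pairs: int = 2,
                    beads_per_chrom: int = 100, seed: int = 0,
                    territory_radius: float = 4.0, spacing: float = 12.0,
                    ) -> tuple[GenomeModel, list[tuple[str, str]]]:
    """Confined random-walk chromosomes with planted open-Hopf pairs.

    Chromosomes occupy disjoint cubic-grid territories; for each planted
    pair the two chains are replaced by slightly opened, jittered Hopf
    circles sharing one territory, so the planted pairs (returned as ground
    truth) are the only linked pairs by construction.
    """
    if n_linked_pairs > n_chroms // 2:
        raise ValueError("n_linked_pairs must be <= n_chroms / 2")
    rng = np.random.default_rng(seed)
    names = [chr(ord("a") + i) if i < 26 else f"c{i}" for i in range(n_chroms)]

    side = int(np.ceil(n_chroms ** (1 / 3)))
    centers = []
    for i in range(n_chroms):
        ix, iy, iz = i % side, (i // side) % side, i // (side * side)
        centers.append(np.array([ix, iy, iz], dtype=float) * spacing)

    paired = list(range(2 * n_linked_pairs))
    chroms: list[Chromosome] = []
    truth: list[tuple[str, str]] = []
    k = 0
    while k < len(paired):
        i, j = paired[k], paired[k + 1]
        a, b = hopf_pair(beads_per_chrom, radius=territory_radius / 2,
                         center=centers[i])
        for idx, closed in ((i, a), (j, b)):
            chain = open_chain(closed, gap_fraction=0.02, rng=rng,
                               noise_sd=territory_radius * 0.01)
            chroms.append(Chromosome(name=names[idx], chain=chain))
        truth.append((names[i], names[j]))
        k += 2
    for i in range(2 * n_linked_pairs, n_chroms):
        chain = _confined_walk(rng, beads_per_chrom, centers[i],
                               territory_radius)
        chroms.append(Chromosome(name=names[i], chain=chain))
    chroms.sort(key=lambda c: c.name)
    model = GenomeModel(cell_id=f"toy{seed}", model_id="1",
                        chromosomes=chroms)
    return model, truth


def _confined_walk(rng: np.random.Generator, n: int, center: np.ndarray,
                   radius: float, step: float | None = None) -> Polyline:
    step = step or radius / 4
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        for _attempt in range(100):
            d = rng.normal(size=3)
            cand = pts[-1] + d / np.linalg.norm(d) * step
            if np.linalg.norm(cand) <= radius:
                pts.append(cand)
                break
        else:
            raise RuntimeError("confined walk failed to stay in territory")
    return Polyline(np.asarray(pts) + center, closed=False)
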