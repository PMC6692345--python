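"""Closing open chains so closed-curve invariants apply.

Three constructions are provided:

* ``close_direct`` — join the endpoints by the shortest segment;
* ``close_com`` — push each endpoint radially (away from the chain's center
  of mass) onto a large sphere and join the two sphere points by the shorter
  great-circle arc;
* ``close_random`` — join both endpoints to one point drawn uniformly on a
  huge sphere around the whole system; repeated with fresh points, this
  underlies the random-closure consensus used for link typing.

All methods leave the original vertices untouched and only append.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_io import Polyline

__all__ = ["ClosureSpec", "close_direct", "close_com", "close_random",
           "system_sphere", "sample_sphere_point"]

_COINCIDENT = 1e-9


@dataclass
class ClosureSpec:
    """Parameters of the closure procedure used for consensus typing."""

    method: str = "random"
    sphere_radius_factor: float = 10.0
    n_random: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("direct", "center_of_mass", "random"):
            raise ValueError(f"unknown closure method {self.method!r}")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.sphere_radius_factor < 2:
            raise ValueError("sphere_radius_factor must be >= 2")


def close_direct(chain: Polyline) -> Polyline:
    """Close by the straight endpoint-joining segment (implicit)."""
    if chain.closed:
        raise ValueError("chain is already closed")
    v = chain.vertices
    if np.linalg.norm(v[0] - v[-1]) <= _COINCIDENT:
        return Polyline(v[:-1], closed=True)
    return Polyline(v, closed=True)


def close_com(chain: Polyline, sphere_radius_factor: float = 10.0) -> Polyline:
    """Center-of-mass closure through a sphere far outside the chain.

    Endpoints are extended radially from the chain's center of mass to a
    sphere of radius ``sphere_radius_factor`` times the maximal bead distance
    from the center, then connected along the shorter great-circle arc
    (discretized at <= 5 degree steps).  Antipodal sphere points are joined
    through a deterministic perpendicular waypoint.
    """
    if chain.closed:
        raise ValueError("chain is already closed")
    v = chain.vertices
    com = v.mean(axis=0)
    radius = sphere_radius_factor * float(np.max(np.linalg.norm(v - com, axis=1)))
    ends = []
    for p in (v[-1], v[0]):
        d = p - com
        norm = np.linalg.norm(d)
        if norm <= _COINCIDENT:
            raise ValueError("endpoint coincides with the center of mass")
        ends.append(com + d / norm * radius)
    a, b = ends
    ua, ub = (a - com) / radius, (b - com) / radius
    cosang = float(np.clip(ua @ ub, -1.0, 1.0))
    angle = np.arccos(cosang)
    if angle < 1e-8:
        pts = [a]  # endpoints on the same radial ray
    elif np.pi - angle < 1e-6:
        # antipodal: route through a deterministic perpendicular waypoint
        w = np.cross(ua, [1.0, 0.0, 0.0])
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(ua, [0.0, 1.0, 0.0])
        w /= np.linalg.norm(w)
        pts = _great_arc(com, radius, ua, w) + _great_arc(com, radius, w, ub)[1:]
    else:
        pts = _great_arc(com, radius, ua, ub)
    # the final arc vertex connects back to v[0] through the implicit segment
    return Polyline(np.vstack([v, pts]), closed=True)


def _great_arc(com, radius, u0, u1, max_step_deg: float = 5.0) -> list:
    """Interior points of the shorter great-circle arc from u0 to u1
    (unit vectors), endpoints included."""
    angle = np.arccos(float(np.clip(u0 @ u1, -1.0, 1.0)))
    n = max(2, int(np.ceil(np.degrees(angle) / max_step_deg)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    sin_a = np.sin(angle)
    pts = []
    for t in ts:
        w = (np.sin((1 - t) * angle) * u0 + np.sin(t * angle) * u1) / sin_a
        pts.append(com + radius * w)
    return pts


def system_sphere(chains: list[Polyline]) -> tuple[np.ndarray, float]:
    """Bounding sphere (center, radius) of all chains under analysis."""
    allv = np.vstack([c.vertices for c in chains])
    center = 0.5 * (allv.min(axis=0) + allv.max(axis=0))
    radius = float(np.max(np.linalg.norm(allv - center, axis=1)))
    return center, max(radius, 1e-9)


def sample_sphere_point(rng: np.random.Generator, center: np.ndarray,
                        radius: float) -> np.ndarray:
    u = rng.normal(size=3)
    return center + radius * u / np.linalg.norm(u)


def close_random(chain: Polyline, rng: np.random.Generator,
                 sphere_radius_factor: float = 10.0,
                 system: list[Polyline] | None = None) -> Polyline:
    """Random one-point closure on a huge sphere around the whole system.

    The sphere is centered on the bounding sphere of ``system`` (all chains
    being analysed together; defaults to the chain itself) with radius
    ``sphere_radius_factor`` times the bounding radius, so simultaneous
    closures of several chains live on the same sphere.
    """
    if chain.closed:
        raise ValueError("chain is already closed")
    center, radius = system_sphere(system or [chain])
    point = sample_sphere_point(rng, center, sphere_radius_factor * radius)
    return Polyline(np.vstack([chain.vertices, point[None, :]]), closed=True)
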