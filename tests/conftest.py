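import numpy as np
import pytest

from chromolink.chain_io import Polyline
from chromolink.synthetic import hopf_pair, torus_curve, torus_link


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hopf_closed():
    """Two interlocked perpendicular circles, 200 beads each."""
    return hopf_pair(200, radius=1.0)


@pytest.fixture
def solomon_closed():
    """(2, 4) torus link, 400 beads per component."""
    return torus_link(2, 400)


@pytest.fixture
def trefoil_closed():
    return torus_curve(2, 3, 120)


def random_open_chain(rng, n, step=1.0, start=(0.0, 0.0, 0.0)):
    """Random walk with unit steps; generic (no collinear triples)."""
    pts = [np.asarray(start, dtype=float)]
    for _ in range(n - 1):
        d = rng.normal(size=3)
        pts.append(pts[-1] + d / np.linalg.norm(d) * step)
    return Polyline(np.asarray(pts))


def open_hopf_pair(n=80, radius=2.0):
    """Open Hopf rings with 1-bead gaps rotated to face away from the
    partner ring, so closure legs rarely thread it."""
    a, b = hopf_pair(n, radius=radius)
    a = Polyline(np.roll(a.vertices, n // 2, axis=0), closed=True)
    b = Polyline(np.roll(b.vertices, n // 2, axis=0), closed=True)
    from chromolink.synthetic import open_chain
    return open_chain(a, 1 / n), open_chain(b, 1 / n)


def quadrature_gln(s1, s2, n=200):
    """Brute-force midpoint quadrature of the Gauss integral over two
    segments; independent oracle for the analytic solid-angle formula."""
    p0, p1 = (np.asarray(p, float) for p in s1)
    q0, q1 = (np.asarray(q, float) for q in s2)
    u = (np.arange(n) + 0.5) / n
    a = p0 + u[:, None] * (p1 - p0)
    b = q0 + u[:, None] * (q1 - q0)
    da = (p1 - p0) / n
    db = (q1 - q0) / n
    diff = a[:, None, :] - b[None, :, :]
    num = diff @ np.cross(da, db)
    den = np.linalg.norm(diff, axis=-1) ** 3
    return float(np.sum(num / den)) / (4 * np.pi)
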