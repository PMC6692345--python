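"""HOMFLY-PT evaluation by skein-tree recursion over crossing diagrams.

Convention (fixed throughout the package):

    l P(L+) + l^-1 P(L-) + m P(L0) = 0,     P(unknot) = 1,
    P(L1 u L2) = delta P(L1) P(L2),         delta = -(l + l^-1)/m.

The recursion drives the diagram toward a descending one (every crossing
first met on its over strand), which is an unlink; Reidemeister I/II
reduction, split-diagram factorization and memoization on canonical diagram
codes keep the tree small.
"""

from __future__ import annotations

import numpy as np

from ..chain_io import Polyline
from .diagram import Diagram, NonGenericProjection, TooComplex
from .poly import ONE, LaurentPoly2, delta
from .project import project_diagram, random_direction

__all__ = ["homfly_pt", "homfly_of_chains", "MAX_CROSSINGS"]

#: crossing budget after simplification; beyond it the link is binned "Other"
MAX_CROSSINGS = 15


def homfly_pt(diagram: Diagram, max_crossings: int = MAX_CROSSINGS) -> LaurentPoly2:
    """HOMFLY-PT polynomial of a diagram.

    Raises :class:`TooComplex` when the simplified diagram still has more
    than ``max_crossings`` crossings.
    """
    memo: dict[str, LaurentPoly2] = {}
    d = diagram.simplify()
    if d.n_crossings > max_crossings:
        raise TooComplex(f"{d.n_crossings} crossings after simplification")
    return _eval(d, memo, max_crossings)


def _eval(d: Diagram, memo: dict[str, LaurentPoly2],
          budget: int) -> LaurentPoly2:
    key = d.key()
    hit = memo.get(key)
    if hit is not None:
        return hit

    groups = d.split_groups()
    if len(groups) > 1:
        out = ONE
        for g in groups:
            out = out * _eval(g, memo, budget)
        out = out * delta ** (len(groups) - 1)
        memo[key] = out
        return out

    bad = d.first_bad_crossing()
    if bad is None:
        # descending connected diagram: an unlink of its components
        out = delta ** (d.n_components - 1)
        memo[key] = out
        return out

    sign = d.sign_of(bad)
    switched = d.switch(bad).simplify()
    smoothed = d.smooth(bad).simplify()
    for child in (switched, smoothed):
        if child.n_crossings > budget:
            raise TooComplex(f"{child.n_crossings} crossings in skein tree")
    p_sw = _eval(switched, memo, budget)
    p_sm = _eval(smoothed, memo, budget)
    if sign > 0:
        #  P(L+) = -l^-2 P(L-) - l^-1 m P(L0)
        out = p_sw.shift(-2, 0).scale(-1) + p_sm.shift(-1, 1).scale(-1)
    else:
        #  P(L-) = -l^2 P(L+) - l m P(L0)
        out = p_sw.shift(2, 0).scale(-1) + p_sm.shift(1, 1).scale(-1)
    memo[key] = out
    return out


def homfly_of_chains(chains: list[Polyline],
                     rng: np.random.Generator | None = None,
                     direction: np.ndarray | None = None,
                     max_retries: int = 50,
                     max_crossings: int = MAX_CROSSINGS) -> LaurentPoly2:
    """Project closed chains generically and evaluate HOMFLY-PT.

    A fixed ``direction`` may be supplied; otherwise directions are sampled
    from ``rng`` until one is generic (at most ``max_retries`` attempts).
    """
    if direction is not None:
        return homfly_pt(project_diagram(chains, direction), max_crossings)
    if rng is None:
        rng = np.random.default_rng()
    last: Exception | None = None
    for _ in range(max_retries):
        try:
            diagram = project_diagram(chains, random_direction(rng))
        except NonGenericProjection as exc:
            last = exc
            continue
        return homfly_pt(diagram, max_crossings)
    raise NonGenericProjection(
        f"no generic projection after {max_retries} attempts: {last}")
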