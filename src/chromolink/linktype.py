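"""Link/knot typing of open chains by random-closure consensus.

Each trial closes every chain through one random point on a huge common
sphere, simplifies the closed system with obstacle-aware KMT, projects along
a random generic direction, evaluates the HOMFLY-PT polynomial and names the
type.  The consensus over many closures (default 100) is reported as a
frequency map; diagrams beyond the crossing budget are binned as ``Other``,
matching how overly complex links are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_io import Polyline
from .closures import ClosureSpec, close_com, close_direct, close_random
from .homfly import NonGenericProjection, TooComplex, classify, homfly_of_chains
from .kmt import kmt

__all__ = ["ConsensusResult", "link_type_consensus", "knot_type_single",
           "type_closed_chains"]


@dataclass
class ConsensusResult:
    """Frequencies of named link types over random closures."""

    frequencies: dict[str, float]
    n_closures: int
    dominant: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("empty consensus")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        best = max(self.frequencies.values())
        self.dominant = min(n for n, f in self.frequencies.items()
                            if f == best)  # ties -> lexicographic


def type_closed_chains(chains: list[Polyline],
                       rng: np.random.Generator) -> str:
    """Name the link type of already-closed chains (KMT + HOMFLY + table)."""
    reduced = []
    for i, ch in enumerate(chains):
        obstacles = reduced + chains[i + 1:]
        reduced.append(kmt(ch, obstacles).chain)
    try:
        poly = homfly_of_chains(reduced, rng=rng)
    except TooComplex:
        return "Other"
    return classify(poly, len(chains)).name


def link_type_consensus(chains: tuple[Polyline, Polyline] | list[Polyline],
                        spec: ClosureSpec | None = None,
                        rng: np.random.Generator | None = None
                        ) -> ConsensusResult:
    """Random-closure consensus link type of a pair of open chains.

    Each chain of the pair receives its own random sphere point per trial;
    the sphere is shared (it bounds the whole pair), so the straight closure
    legs cannot interleave inside the data region.
    """
    spec = spec or ClosureSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    chains = list(chains)
    if any(c.closed for c in chains):
        raise ValueError("consensus typing expects open chains")
    counts: dict[str, int] = {}
    failures = 0
    for _ in range(spec.n_random):
        closed = [close_random(c, rng, spec.sphere_radius_factor,
                               system=chains) for c in chains]
        try:
            name = type_closed_chains(closed, rng)
        except NonGenericProjection:
            failures += 1
            continue
        counts[name] = counts.get(name, 0) + 1
    if failures > spec.n_random / 2:
        raise RuntimeError(
            f"{failures}/{spec.n_random} closures failed to project")
    n_ok = sum(counts.values())
    freqs = {k: v / n_ok for k, v in counts.items()}
    return ConsensusResult(frequencies=freqs, n_closures=n_ok)


def knot_type_single(chain: Polyline, method: str = "com",
                     spec: ClosureSpec | None = None,
                     rng: np.random.Generator | None = None
                     ) -> ConsensusResult:
    """Knot type of a single open chain.

    ``method="com"`` (the usual choice for single chromosomes) closes once
    through the center-of-mass sphere and reports that type with frequency
    1; ``method="random"`` runs the full random-closure consensus.
    """
    spec = spec or ClosureSpec(method="center_of_mass")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if chain.closed:
        raise ValueError("chain is already closed")
    if method == "com":
        closed = close_com(chain, spec.sphere_radius_factor)
        name = type_closed_chains([closed], rng)
        return ConsensusResult(frequencies={name: 1.0}, n_closures=1)
    if method == "random":
        counts: dict[str, int] = {}
        failures = 0
        for _ in range(spec.n_random):
            closed = close_random(chain, rng, spec.sphere_radius_factor)
            try:
                name = type_closed_chains([closed], rng)
            except NonGenericProjection:
                failures += 1
                continue
            counts[name] = counts.get(name, 0) + 1
        if failures > spec.n_random / 2:
            raise RuntimeError("most closures failed to project")
        n_ok = sum(counts.values())
        return ConsensusResult(
            frequencies={k: v / n_ok for k, v in counts.items()},
            n_closures=n_ok)
    raise ValueError(f"unknown method {method!r}")


def close_pair_direct(chains: list[Polyline]) -> list[Polyline]:
    """Direct closure of each chain of a pair (single-diagram typing)."""
    return [close_direct(c) for c in chains]
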