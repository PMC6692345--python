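"""Genome-wide link survey: pairwise GLN, link calling, typing, localization,
multi-component link graphs, and cross-model conservation.

A pair of chromosomes is called linked when |GLN| >= 0.7 (the threshold is a
parameter; values near 1 indicate Hopf-like, near 2 Solomon-like winding).
Linked pairs are optionally typed by random-closure consensus and localized
to the shortest fragment pair retaining the whole-chain GLN.  Groups of >= 3
chromosomes connected by linked pairs are reported as multiple links.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chain_io import GenomeModel, LinkRecord
from .closures import ClosureSpec
from .gln import DegenerateGeometry, fragment_table, localize_link
from .linktype import link_type_consensus

__all__ = ["survey", "gln_histogram", "multi_links", "conservation",
           "closure_preservation_estimate", "LinkGraph", "ConservationReport",
           "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.7


def survey(model: GenomeModel, threshold: float = DEFAULT_THRESHOLD,
           type_linked: bool = False, localize: bool = True,
           closure_spec: ClosureSpec | None = None,
           rng: np.random.Generator | None = None) -> list[LinkRecord]:
    """Pairwise GLN over all C(n, 2) chromosome pairs of one model.

    Pairs with |GLN| >= ``threshold`` are flagged as linked; those get
    localization and (if ``type_linked``) random-closure consensus typing.
    Records are sorted by |GLN| descending.  Pairs with degenerate geometry
    (overlapping chains) are skipped with a warning record left out.
    """
    if len(model.chromosomes) < 2:
        raise ValueError("survey needs at least 2 chromosomes")
    if rng is None:
        rng = np.random.default_rng(closure_spec.seed if closure_spec else 0)
    records: list[LinkRecord] = []
    chroms = model.chromosomes
    for i in range(len(chroms)):
        for j in range(i + 1, len(chroms)):
            a, b = chroms[i], chroms[j]
            try:
                table = fragment_table(a.chain, b.chain)
            except DegenerateGeometry:
                import warnings
                warnings.warn(f"pair {a.name}-{b.name}: degenerate geometry, "
                              "skipped", stacklevel=2)
                continue
            g = table.total
            linked = abs(g) >= threshold
            rec = LinkRecord(pair=(a.name, b.name), gln=g, linked=linked)
            if linked and localize:
                rec.localization = localize_link(table)
            if linked and type_linked:
                cons = link_type_consensus(
                    (a.chain, b.chain), closure_spec, rng=rng)
                rec.consensus = cons.frequencies
                rec.dominant = cons.dominant
            records.append(rec)
    records.sort(key=lambda r: -abs(r.gln))
    return records


def gln_histogram(records: list[LinkRecord], bin_width: float = 0.1,
                  threshold: float = DEFAULT_THRESHOLD):
    """Histogram of |GLN| with cumulative fractions and summary shares.

    Returns ``(edges, counts, cumulative, summary)`` where ``cumulative`` is
    the cumulative probability at each bin's upper edge and ``summary`` holds
    the fractions of pairs with |GLN| < 0.5 and >= ``threshold``.
    """
    if not records:
        raise ValueError("no records to histogram")
    vals = np.array([abs(r.gln) for r in records])
    top = max(bin_width, float(vals.max()) + bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    cumulative = np.cumsum(counts) / len(vals)
    summary = {
        "n_pairs": len(vals),
        "fraction_below_0.5": float(np.mean(vals < 0.5)),
        "fraction_linked": float(np.mean(vals >= threshold)),
    }
    return edges, counts, cumulative, summary


@dataclass
class LinkGraph:
    """Chromosomes as nodes, linked pairs as edges; components of >= 3
    chromosomes are the multiple links."""

    graph: nx.Graph

    @property
    def multiple_links(self) -> list[dict]:
        out = []
        for comp in nx.connected_components(self.graph):
            if len(comp) < 3:
                continue
            sub = self.graph.subgraph(comp)
            out.append({
                "chromosomes": sorted(comp),
                "edges": sorted(tuple(sorted(e)) for e in sub.edges),
                "degrees": {n: int(sub.degree[n]) for n in sorted(comp)},
            })
        out.sort(key=lambda c: (-len(c["chromosomes"]), c["chromosomes"]))
        return out


def multi_links(records: list[LinkRecord]) -> LinkGraph:
    """Build the link graph from one model's records (linked edges only)."""
    g = nx.Graph()
    for r in records:
        g.add_node(r.pair[0])
        g.add_node(r.pair[1])
        if r.linked:
            g.add_edge(*r.pair, gln=r.gln)
    return LinkGraph(graph=g)


@dataclass
class ConservationReport:
    """Per-pair linked-model counts across the models of one cell."""

    n_models: int
    counts: dict[tuple[str, str], int]
    glns: dict[tuple[str, str], list[float]]

    @property
    def stable_pairs(self) -> list[tuple[str, str]]:
        return sorted(p for p, c in self.counts.items() if c == self.n_models)

    def count(self, a: str, b: str) -> int:
        return self.counts.get(tuple(sorted((a, b))), 0)


def conservation(models: list[GenomeModel],
                 threshold: float = DEFAULT_THRESHOLD) -> ConservationReport:
    """Link reproducibility across models: in how many models is each pair
    linked, and which pairs are linked in all of them."""
    if not models:
        raise ValueError("no models")
    names = set(models[0].names)
    for m in models[1:]:
        if set(m.names) != names:
            raise ValueError(
                f"model {m.cell_id}/{m.model_id} chromosome names differ")
    counts: dict[tuple[str, str], int] = {}
    glns: dict[tuple[str, str], list[float]] = {}
    for m in models:
        for r in survey(m, threshold=threshold, localize=False):
            key = tuple(sorted(r.pair))
            glns.setdefault(key, []).append(r.gln)
            if r.linked:
                counts[key] = counts.get(key, 0) + 1
    return ConservationReport(n_models=len(models), counts=counts, glns=glns)


def closure_preservation_estimate(p1: float, p2: float,
                                  f_cross: float) -> float:
    """Probability that random closures leave a pair's link type unaffected.

    ``p1`` and ``p2`` are the per-chain knot-type probabilities and
    ``f_cross`` the fraction of closure directions that pass through the
    partner chromosome; both closures must individually preserve their chain
    and miss the partner, hence ``p1 p2 (1 - f_cross)^2``.
    """
    for name, v in (("p1", p1), ("p2", p2), ("f_cross", f_cross)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return p1 * p2 * (1.0 - f_cross) ** 2
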