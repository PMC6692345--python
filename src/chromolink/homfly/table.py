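"""Self-generated link-type table: HOMFLY-PT polynomial -> name.

Every base entry is computed by this package's own projection + skein engine
from a geometric canonical construction (torus-curve or braid-closure
realizations), so the table is automatically in the engine's variable
convention.  Composite (#) and split (U) entries are derived from the base
polynomials through the product and delta rules.  Mirror images share the
field's unsigned names (``3_1``, ``Hopf``, ...).

Scope: prime knots up to 7 crossings (less 7_2-7_7), 2-component prime links
up to 6 crossings plus the Whitehead link, and their # / U combinations up
to 9 total crossings.  Anything else classifies as ``Other``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path

from .braid import braid_curves
from .engine import homfly_of_chains
from .poly import ONE, LaurentPoly2, delta

__all__ = ["LinkTypeResult", "classify", "build_table", "load_table", "save_table"]

_DIRECTION = (0.0, 0.0, 1.0)  # braid embeddings are generic along +z

#: braid words of the base (prime, possibly chiral) knots and links
_BASE_KNOTS: dict[str, tuple[list[int], int]] = {
    "3_1": ([1, 1, 1], 3),
    "4_1": ([1, -2, 1, -2], 4),
    "5_1": ([1, 1, 1, 1, 1], 5),
    "5_2": ([1, 1, 1, 2, -1, 2], 5),
    "6_1": ([1, 1, 2, -1, -3, 2, -3], 6),
    "6_2": ([1, 1, 1, -2, 1, -2], 6),
    "6_3": ([1, 1, -2, 1, -2, -2], 6),
    "7_1": ([1, 1, 1, 1, 1, 1, 1], 7),
}
_BASE_LINKS: dict[str, tuple[list[int], int]] = {
    "Hopf": ([1, 1], 2),
    "Solomon": ([1, 1, 1, 1], 4),
    "Whitehead": ([1, -2, 1, -2, 1], 5),
    "6^2_1": ([1, 1, 1, 1, 1, 1], 6),
}


@dataclass(frozen=True)
class LinkTypeResult:
    """A named link topology; ``Other`` marks anything outside the table."""

    name: str
    n_components: int


def _variants(p: LaurentPoly2) -> list[LaurentPoly2]:
    """Polynomial together with its mirror (deduplicated for amphichirals)."""
    m = p.mirror()
    return [p] if m == p else [p, m]


def _base_polynomials() -> tuple[dict, dict]:
    knots = {"0_1": ([ONE], 0)}
    for name, (word, nc) in _BASE_KNOTS.items():
        p = homfly_of_chains(braid_curves(word), direction=_DIRECTION)
        knots[name] = (_variants(p), nc)
    links = {}
    for name, (word, nc) in _BASE_LINKS.items():
        p = homfly_of_chains(braid_curves(word), direction=_DIRECTION)
        links[name] = (_variants(p), nc)
    return knots, links


def _sorted_factors(names: list[str]) -> list[str]:
    # smaller factors first, as in "3_1 # 4_1 # Hopf"
    return sorted(names, key=lambda n: (int(n.split("_")[0].split("^")[0])
                                        if n[0].isdigit() else 99, n))


def build_table(max_total_crossings: int = 9) -> dict[str, str]:
    """Generate the full lookup table ``"ncomp|polykey" -> name``."""
    knots, links = _base_polynomials()
    entries: dict[str, str] = {}

    def put(ncomp: int, poly: LaurentPoly2, name: str) -> None:
        key = f"{ncomp}|{poly.key()}"
        prev = entries.get(key)
        if prev is not None and prev != name:
            raise RuntimeError(
                f"polynomial collision: {prev!r} vs {name!r} ({key})")
        entries[key] = name

    # single-component: prime knots and their connected sums
    for name, (variants, nc) in knots.items():
        for p in variants:
            put(1, p, name)
    for (na, (va, ca)), (nb, (vb, cb)) in combinations_with_replacement(
            sorted(knots.items()), 2):
        if na == "0_1" or nb == "0_1" or ca + cb > 7:
            continue
        name = " # ".join(_sorted_factors([na, nb]))
        for pa in va:
            for pb in vb:
                put(1, pa * pb, name)

    # two components: (knot # knot # prime-link) and split unions
    link_options = [("U", [None], 0)] + [
        (n, v, c) for n, (v, c) in sorted(links.items())]
    for (na, (va, ca)), (nb, (vb, cb)) in combinations_with_replacement(
            sorted(knots.items()), 2):
        for ln, lvars, lc in link_options:
            if ca + cb + lc > max_total_crossings:
                continue
            if ln == "U":
                if na == nb == "0_1":
                    name = "U"
                else:
                    name = " U ".join(_sorted_factors([na, nb]))
                for pa in va:
                    for pb in vb:
                        put(2, delta * pa * pb, name)
            else:
                factors = [n for n in (na, nb) if n != "0_1"]
                name = " # ".join(_sorted_factors(factors) + [ln]) \
                    if factors else ln
                for pa in va:
                    for pb in vb:
                        for pl in lvars:
                            put(2, pa * pb * pl, name)
    return entries


# ---------------------------------------------------------------------------
# persistence

_TABLE_CACHE: dict[str, str] | None = None
_DATA_NAME = "link_table.json"


def save_table(entries: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"format": 1, "entries": entries}, fh, indent=0, sort_keys=True)


def load_table() -> dict[str, str]:
    """Shipped table, built on the fly if the data file is absent."""
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        try:
            ref = resources.files("chromolink.data").joinpath(_DATA_NAME)
            _TABLE_CACHE = json.loads(ref.read_text())["entries"]
        except (FileNotFoundError, ModuleNotFoundError):
            _TABLE_CACHE = build_table()
    return _TABLE_CACHE


def classify(poly: LaurentPoly2, n_components: int,
             table: dict[str, str] | None = None) -> LinkTypeResult:
    """Name the link type of a HOMFLY-PT polynomial, or ``Other``."""
    table = table if table is not None else load_table()
    name = table.get(f"{n_components}|{poly.key()}", "Other")
    return LinkTypeResult(name=name, n_components=n_components)
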