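"""Combinatorial link diagrams as per-component crossing sequences.

A diagram is a tuple of components; each component is the cyclic sequence of
crossing passes met while walking the oriented strand.  A pass is
``(crossing_id, role, sign)`` with role ``'o'`` (over) or ``'u'`` (under) and
sign +-1 by the right-hand rule.  Every crossing id appears exactly twice in
the whole diagram, once over and once under.  Components without passes are
crossing-free circles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["Diagram", "Pass", "NonGenericProjection", "TooComplex"]

Pass = tuple[int, str, int]  # (crossing id, 'o'|'u', sign)


class NonGenericProjection(RuntimeError):
    """Projection direction produced a degenerate diagram; resample."""


class TooComplex(RuntimeError):
    """Diagram exceeds the crossing budget for skein recursion."""


@dataclass(frozen=True)
class Diagram:
    components: tuple[tuple[Pass, ...], ...]

    # -- basic queries -------------------------------------------------------
    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_crossings(self) -> int:
        return sum(len(c) for c in self.components) // 2

    def crossing_ids(self) -> set[int]:
        return {p[0] for comp in self.components for p in comp}

    def validate(self) -> None:
        seen: dict[int, list[str]] = {}
        for comp in self.components:
            for cid, role, sign in comp:
                seen.setdefault(cid, []).append(role)
        for cid, roles in seen.items():
            if sorted(roles) != ["o", "u"]:
                raise ValueError(f"crossing {cid} roles {roles}")

    def sign_of(self, cid: int) -> int:
        for comp in self.components:
            for p in comp:
                if p[0] == cid:
                    return p[2]
        raise KeyError(cid)

    # -- crossing moves ------------------------------------------------------
    def switch(self, cid: int) -> "Diagram":
        """Exchange over/under at one crossing (negates its sign)."""
        flip = {"o": "u", "u": "o"}
        comps = tuple(
            tuple((c, flip[r], -s) if c == cid else (c, r, s) for c, r, s in comp)
            for comp in self.components
        )
        return Diagram(comps)

    def smooth(self, cid: int) -> "Diagram":
        """Oriented smoothing: reconnect the two strands respecting orientation."""
        locs = []
        for ci, comp in enumerate(self.components):
            for pi, p in enumerate(comp):
                if p[0] == cid:
                    locs.append((ci, pi))
        if len(locs) != 2:
            raise KeyError(cid)
        (c1, i), (c2, j) = locs
        comps = list(self.components)
        if c1 != c2:
            A, B = comps[c1], comps[c2]
            merged = A[i + 1:] + A[:i] + B[j + 1:] + B[:j]
            keep = [comp for k, comp in enumerate(comps) if k not in (c1, c2)]
            comps = keep + [merged]
        else:
            A = comps[c1]
            if i > j:
                i, j = j, i
            first = A[j + 1:] + A[:i]
            second = A[i + 1:j]
            comps = [comp for k, comp in enumerate(comps) if k != c1]
            comps += [first, second]
        return Diagram(tuple(tuple(c) for c in comps))

    # -- Reidemeister simplification ----------------------------------------
    def _r1_once(self) -> "Diagram | None":
        for ci, comp in enumerate(self.components):
            L = len(comp)
            for k in range(L):
                if L >= 2 and comp[k][0] == comp[(k + 1) % L][0]:
                    cid = comp[k][0]
                    new = tuple(p for p in comp if p[0] != cid)
                    comps = list(self.components)
                    comps[ci] = new
                    return Diagram(tuple(comps))
        return None

    def _adjacent_pairs(self) -> list[tuple[int, int, int, int]]:
        """All (comp, pos, cid_at_pos, cid_at_next) cyclic adjacencies."""
        out = []
        for ci, comp in enumerate(self.components):
            L = len(comp)
            if L < 2:
                continue
            for k in range(L):
                out.append((ci, k, comp[k][0], comp[(k + 1) % L][0]))
        return out

    def _r2_once(self) -> "Diagram | None":
        pairs = self._adjacent_pairs()
        index: dict[frozenset, list[tuple[int, int, int, int]]] = {}
        for item in pairs:
            ci, k, a, b = item
            if a == b:
                continue
            index.setdefault(frozenset((a, b)), []).append(item)
        for key, items in index.items():
            if len(items) < 2:
                continue
            for ia in range(len(items)):
                for ib in range(ia + 1, len(items)):
                    ci1, k1, a1, b1 = items[ia]
                    ci2, k2, a2, b2 = items[ib]
                    if ci1 == ci2:
                        L = len(self.components[ci1])
                        span1 = {k1, (k1 + 1) % L}
                        span2 = {k2, (k2 + 1) % L}
                        if span1 & span2:
                            continue
                    x, y = a1, b1
                    comp1 = self.components[ci1]
                    comp2 = self.components[ci2]
                    L1, L2 = len(comp1), len(comp2)
                    p1x, p1y = comp1[k1], comp1[(k1 + 1) % L1]
                    q = (comp2[k2], comp2[(k2 + 1) % L2])
                    # align q to (x, y) order
                    if q[0][0] == x:
                        q_x, q_y = q
                    else:
                        q_y, q_x = q
                    # one strand passes over both, the other under both
                    if p1x[1] != p1y[1] or q_x[1] != q_y[1] or p1x[1] == q_x[1]:
                        continue
                    if p1x[2] != -p1y[2]:
                        continue
                    comps = tuple(
                        tuple(p for p in comp if p[0] not in (x, y))
                        for comp in self.components
                    )
                    return Diagram(comps)
        return None

    def simplify(self) -> "Diagram":
        """Apply Reidemeister I/II reductions until none applies."""
        d = self
        while True:
            nxt = d._r1_once()
            if nxt is not None:
                d = nxt
                continue
            nxt = d._r2_once()
            if nxt is not None:
                d = nxt
                continue
            return d

    # -- split structure -----------------------------------------------------
    def split_groups(self) -> list["Diagram"]:
        """Partition components into groups connected by shared crossings."""
        n = len(self.components)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        where: dict[int, int] = {}
        for ci, comp in enumerate(self.components):
            for cid, _, _ in comp:
                if cid in where:
                    ra, rb = find(where[cid]), find(ci)
                    parent[ra] = rb
                else:
                    where[cid] = ci
        groups: dict[int, list] = {}
        for ci in range(n):
            groups.setdefault(find(ci), []).append(self.components[ci])
        return [Diagram(tuple(comps)) for _, comps in sorted(groups.items())]

    # -- descending traversal ------------------------------------------------
    def first_bad_crossing(self) -> int | None:
        """First crossing met on its under-strand before its over-strand.

        Components are walked in order from their stored basepoints; a
        diagram with no bad crossing is descending and represents an unlink.
        """
        seen: set[int] = set()
        for comp in self.components:
            for cid, role, _ in comp:
                if cid not in seen:
                    if role == "u":
                        return cid
                    seen.add(cid)
        return None

    # -- canonical key -------------------------------------------------------
    def key(self) -> str:
        """Deterministic serialization with crossings relabeled by first
        appearance; used for memoization (equal keys => equal diagrams)."""
        label: dict[int, int] = {}
        parts = []
        for comp in self.components:
            bits = []
            for cid, role, sign in comp:
                if cid not in label:
                    label[cid] = len(label)
                bits.append(f"{label[cid]}{role}{'+' if sign > 0 else '-'}")
            parts.append(",".join(bits))
        return "|".join(parts)

    @classmethod
    def from_components(cls, comps: Iterable[Iterable[Pass]]) -> "Diagram":
        d = cls(tuple(tuple(c) for c in comps))
        d.validate()
        return d
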