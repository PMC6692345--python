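"""Exact integer Laurent polynomials in the two HOMFLY-PT variables (l, m)."""

from __future__ import annotations

from typing import Iterable, Mapping

__all__ = ["LaurentPoly2", "delta", "ONE", "ZERO"]


class LaurentPoly2:
    """Immutable Laurent polynomial with integer coefficients in l and m.

    Terms map exponent pairs ``(dl, dm)`` (possibly negative) to nonzero
    integer coefficients.  All arithmetic is exact.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[tuple[int, int], int] | None = None):
        clean = {k: int(v) for k, v in (terms or {}).items() if v != 0}
        object.__setattr__(self, "terms", clean)

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("LaurentPoly2 is immutable")

    # -- constructors -------------------------------------------------------
    @classmethod
    def monomial(cls, dl: int, dm: int, coeff: int = 1) -> "LaurentPoly2":
        return cls({(dl, dm): coeff})

    @classmethod
    def const(cls, c: int) -> "LaurentPoly2":
        return cls({(0, 0): c})

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "LaurentPoly2") -> "LaurentPoly2":
        out = dict(self.terms)
        for k, v in other.terms.items():
            out[k] = out.get(k, 0) + v
        return LaurentPoly2(out)

    def __sub__(self, other: "LaurentPoly2") -> "LaurentPoly2":
        out = dict(self.terms)
        for k, v in other.terms.items():
            out[k] = out.get(k, 0) - v
        return LaurentPoly2(out)

    def __neg__(self) -> "LaurentPoly2":
        return LaurentPoly2({k: -v for k, v in self.terms.items()})

    def __mul__(self, other: "LaurentPoly2") -> "LaurentPoly2":
        out: dict[tuple[int, int], int] = {}
        for (a1, b1), c1 in self.terms.items():
            for (a2, b2), c2 in other.terms.items():
                k = (a1 + a2, b1 + b2)
                out[k] = out.get(k, 0) + c1 * c2
        return LaurentPoly2(out)

    def shift(self, dl: int, dm: int) -> "LaurentPoly2":
        """Multiply by the monomial l^dl m^dm."""
        return LaurentPoly2({(a + dl, b + dm): c for (a, b), c in self.terms.items()})

    def scale(self, c: int) -> "LaurentPoly2":
        return LaurentPoly2({k: c * v for k, v in self.terms.items()})

    def __pow__(self, n: int) -> "LaurentPoly2":
        if n < 0:
            raise ValueError("negative powers not supported")
        out = ONE
        for _ in range(n):
            out = out * self
        return out

    # -- comparisons / hashing ---------------------------------------------
    def __eq__(self, other: object) -> bool:
        return isinstance(other, LaurentPoly2) and self.terms == other.terms

    def __hash__(self) -> int:
        return hash(frozenset(self.terms.items()))

    def __bool__(self) -> bool:
        return bool(self.terms)

    # -- mirror -------------------------------------------------------------
    def mirror(self) -> "LaurentPoly2":
        """Polynomial of the mirror image: l -> l^-1 (m unchanged)."""
        return LaurentPoly2({(-a, b): c for (a, b), c in self.terms.items()})

    # -- serialization -------------------------------------------------------
    def key(self) -> str:
        """Canonical compact string, usable as a lookup key."""
        parts = [f"{a},{b}:{c}" for (a, b), c in sorted(self.terms.items())]
        return ";".join(parts) or "0"

    @classmethod
    def from_key(cls, key: str) -> "LaurentPoly2":
        if key == "0":
            return cls()
        terms = {}
        for part in key.split(";"):
            exps, c = part.split(":")
            a, b = exps.split(",")
            terms[(int(a), int(b))] = int(c)
        return cls(terms)

    def __repr__(self) -> str:
        if not self.terms:
            return "0"
        bits = []
        for (a, b), c in sorted(self.terms.items()):
            mono = "".join(
                (f"l^{e}" if v == "l" else f"m^{e}").replace("^1", "")
                for v, e in (("l", a), ("m", b)) if e
            )
            bits.append(f"{c:+d}{mono}" if mono else f"{c:+d}")
        return "".join(bits)

    def evaluate(self, l: complex, m: complex) -> complex:
        return sum(c * l**a * m**b for (a, b), c in self.terms.items())


ONE = LaurentPoly2.const(1)
ZERO = LaurentPoly2()

#: HOMFLY value of a split union factor: -(l + l^-1)/m
delta = LaurentPoly2({(1, -1): -1, (-1, -1): -1})
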