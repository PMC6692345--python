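"""HOMFLY-PT engine: projection, polynomial arithmetic, skein relation,
split/product structure, classification table, mirror behaviour."""

import numpy as np
import pytest

from chromolink.chain_io import Polyline
from chromolink.gln import gln
from chromolink.homfly import (Diagram, LaurentPoly2, classify, delta,
                               homfly_of_chains, homfly_pt, project_diagram)
from chromolink.homfly.braid import braid_curves
from chromolink.homfly.engine import _eval  # skein internals for spot checks
from chromolink.homfly.poly import ONE
from chromolink.synthetic import (circle, figure8_curve, hopf_pair,
                                  insert_local_knot, torus_curve, torus_link)


class TestLaurentPoly:
    def test_arithmetic_exact(self):
        p = LaurentPoly2({(1, -1): 2, (0, 0): -1})
        q = LaurentPoly2({(-1, 0): 3})
        assert (p + q - q) == p
        assert (p * q).terms == {(0, -1): 6, (-1, 0): -3}
        assert (p * ONE) == p
        assert not (p - p)

    def test_key_round_trip(self):
        p = delta * delta + LaurentPoly2.monomial(3, -2, 7)
        assert LaurentPoly2.from_key(p.key()) == p

    def test_mirror_involution(self):
        p = LaurentPoly2({(2, 1): 1, (-1, 0): 4})
        assert p.mirror().mirror() == p


class TestProjection:
    def test_planar_circle_no_crossings(self):
        d = project_diagram([circle(50)], np.array([0.1, 0.2, 0.97]))
        assert d.n_crossings == 0

    def test_hopf_minimal_two_crossings_same_sign(self, hopf_closed):
        d = project_diagram(hopf_closed, np.array([0.3, 0.5, 0.81]))
        assert d.n_crossings == 2
        signs = {p[2] for comp in d.components for p in comp}
        assert len(signs) == 1

    def test_crossing_count_matches_bruteforce_scan(self, rng):
        chains = [torus_curve(2, 3, 60)]
        direction = np.array([0.2, -0.4, 0.89])
        direction /= np.linalg.norm(direction)
        d = project_diagram(chains, direction)
        # independent O(n^2) scan over projected segment pairs
        e1 = np.cross([0.0, 1.0, 0.0], direction)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        v = chains[0].vertices
        pts = np.c_[v @ e1, v @ e2]
        n = len(pts)
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or (j + 1) % n == i or (i + 1) % n == j:
                    continue
                a0, a1 = pts[i], pts[(i + 1) % n]
                b0, b1 = pts[j], pts[(j + 1) % n]
                u, w, r = a1 - a0, b1 - b0, b0 - a0
                den = u[0] * w[1] - u[1] * w[0]
                if abs(den) < 1e-12:
                    continue
                t = (r[0] * w[1] - r[1] * w[0]) / den
                s = (r[0] * u[1] - r[1] * u[0]) / den
                if 0 < t < 1 and 0 < s < 1:
                    count += 1
        assert d.n_crossings == count

    def test_crossing_signs_sum_to_twice_gln(self, hopf_closed, solomon_closed):
        for chains in (hopf_closed, solomon_closed):
            d = project_diagram(chains, np.array([0.3, 0.5, 0.81]))
            inter = {}
            for ci, comp in enumerate(d.components):
                for cid, role, sign in comp:
                    inter.setdefault(cid, []).append((ci, sign))
            total = sum(v[0][1] for v in inter.values()
                        if v[0][0] != v[1][0]) / 2
            assert total == pytest.approx(gln(*chains), abs=1e-6)


class TestEngine:
    def test_unknot_polynomial_is_one(self):
        assert homfly_pt(Diagram(((),))) == ONE

    def test_two_component_zero_crossing_is_delta(self):
        assert homfly_pt(Diagram(((), ()))) == delta

    def test_projection_invariance_20_directions(self, trefoil_closed):
        polys = {homfly_of_chains([trefoil_closed],
                                  rng=np.random.default_rng(k)).key()
                 for k in range(20)}
        assert len(polys) == 1

    def test_connected_sum_multiplies(self, rng):
        tre = torus_curve(2, 3, 120)
        p1 = homfly_of_chains([tre], rng=np.random.default_rng(0))
        double = insert_local_knot(tre, 10, kind="trefoil", size=0.2)
        p2 = homfly_of_chains([double], rng=np.random.default_rng(1))
        assert p2 in (p1 * p1, p1 * p1.mirror())

    def test_split_union_factorizes_with_delta(self):
        tre = torus_curve(2, 3, 100)
        far = Polyline(tre.vertices + np.array([30.0, 0, 0]), closed=True)
        p1 = homfly_of_chains([tre], rng=np.random.default_rng(0))
        p2 = homfly_of_chains([tre, far], rng=np.random.default_rng(1))
        assert p2 == delta * p1 * p1

    def test_mirror_trefoil_distinguished_gln_negated(self, hopf_closed):
        tre = torus_curve(2, 3, 100)
        mir = Polyline(tre.vertices * np.array([1.0, 1.0, -1.0]), closed=True)
        p = homfly_of_chains([tre], rng=np.random.default_rng(0))
        pm = homfly_of_chains([mir], rng=np.random.default_rng(1))
        assert p != pm and pm == p.mirror()
        a, b = hopf_closed
        am = Polyline(a.vertices * np.array([1.0, 1.0, -1.0]), closed=True)
        bm = Polyline(b.vertices * np.array([1.0, 1.0, -1.0]), closed=True)
        assert gln(am, bm) == pytest.approx(-gln(a, b), abs=1e-9)

    def test_skein_identity_on_random_braid_diagrams(self, rng):
        """l P(L+) + l^-1 P(L-) + m P(L0) = 0 with one crossing switched
        and smoothed, for 10 random small braid closures."""
        checked = 0
        while checked < 10:
            word = [int(rng.integers(1, 3)) * int(rng.choice([-1, 1]))
                    for _ in range(int(rng.integers(3, 6)))]
            diagram = project_diagram(braid_curves(word), (0, 0, 1))
            if diagram.n_crossings == 0:
                continue
            cid = sorted(diagram.crossing_ids())[0]
            sign = diagram.sign_of(cid)
            pos = diagram if sign > 0 else diagram.switch(cid)
            neg = diagram.switch(cid) if sign > 0 else diagram
            zero = diagram.smooth(cid)
            p_pos = homfly_pt(pos)
            p_neg = homfly_pt(neg)
            p_zero = homfly_pt(zero)
            total = (p_pos.shift(1, 0) + p_neg.shift(-1, 0)
                     + p_zero.shift(0, 1))
            assert not total, f"skein violated for word {word}"
            checked += 1


class TestClassification:
    def test_delta_two_components_is_unlink(self):
        assert classify(delta, 2).name == "U"

    def test_named_geometric_links(self, rng):
        cases = [
            ([torus_curve(2, 3, 100)], "3_1"),
            ([torus_curve(2, 5, 150)], "5_1"),
            ([figure8_curve(200)], "4_1"),
            (hopf_pair(80), "Hopf"),
            (torus_link(2, 160), "Solomon"),
            (torus_link(3, 200), "6^2_1"),
        ]
        for chains, expected in cases:
            p = homfly_of_chains(chains, rng=np.random.default_rng(3))
            assert classify(p, len(chains)).name == expected

    def test_split_trefoils_named(self):
        tre = torus_curve(2, 3, 100)
        far = Polyline(tre.vertices + np.array([25.0, 0, 0]), closed=True)
        p = homfly_of_chains([tre, far], rng=np.random.default_rng(0))
        assert classify(p, 2).name == "3_1 U 3_1"

    def test_trefoils_joined_by_hopf_clasp(self, rng):
        """Two Hopf-linked rings each carrying a local trefoil: the composite
        3_1 # 3_1 # Hopf, built purely geometrically."""
        a, b = hopf_pair(90, radius=2.0)
        a = insert_local_knot(a, 45, kind="trefoil", size=0.18)
        b = insert_local_knot(b, 45, kind="trefoil", size=0.18)
        p = homfly_of_chains([a, b], rng=np.random.default_rng(4))
        assert classify(p, 2).name == "3_1 # 3_1 # Hopf"

    def test_unmatched_is_other(self):
        weird = LaurentPoly2({(10, 10): 1})
        assert classify(weird, 2).name == "Other"
        # component mismatch: a knot polynomial looked up as a 2-link
        tre = homfly_of_chains([torus_curve(2, 3, 80)],
                               rng=np.random.default_rng(0))
        assert classify(tre, 2).name == "Other"
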