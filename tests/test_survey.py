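"""Genome-wide survey: pair records, histogram, link graph, conservation,
and the closure-preservation arithmetic."""

import numpy as np
import pytest

from chromolink.chain_io import Chromosome, GenomeModel, Polyline
from chromolink.survey import (closure_preservation_estimate, conservation,
                               gln_histogram, multi_links, survey)
from chromolink.synthetic import circle, hopf_pair, make_toy_genome, open_chain

from conftest import random_open_chain


def _model_of(chains, cell="c", model="1"):
    names = "abcdefghijklmnopqrst"
    return GenomeModel(cell, model, [Chromosome(names[i], c)
                                     for i, c in enumerate(chains)])


@pytest.fixture(scope="module")
def planted_model():
    model, truth = make_toy_genome(6, 1, 60, seed=3)
    return model, truth


class TestSurvey:
    def test_twenty_chromosomes_give_190_records(self):
        model, _ = make_toy_genome(20, 0, 30, seed=1)
        records = survey(model, localize=False)
        assert len(records) == 190

    def test_far_separated_chains_unlinked(self, rng):
        chains = [random_open_chain(rng, 40, start=(60.0 * i, 0, 0))
                  for i in range(5)]
        records = survey(_model_of(chains), localize=False)
        assert len(records) == 10
        assert not any(r.linked for r in records)

    def test_planted_hopf_found_among_four_chains(self, rng):
        a, b = (open_chain(c, 0.02) for c in hopf_pair(60, radius=2.0))
        others = [random_open_chain(rng, 40, start=(50.0 + 40 * i, 0, 0))
                  for i in range(2)]
        records = survey(_model_of([a, b] + others))
        linked = [r for r in records if r.linked]
        assert len(linked) == 1 and set(linked[0].pair) == {"a", "b"}
        assert linked[0].localization is not None

    def test_records_sorted_by_abs_gln(self, planted_model):
        records = survey(planted_model[0], localize=False)
        glns = [abs(r.gln) for r in records]
        assert glns == sorted(glns, reverse=True)

    def test_chromosome_order_does_not_change_magnitudes(self, planted_model):
        model, _ = planted_model
        rev = GenomeModel(model.cell_id, "rev",
                          list(reversed(model.chromosomes)))
        fwd = {frozenset(r.pair): abs(r.gln)
               for r in survey(model, localize=False)}
        bwd = {frozenset(r.pair): abs(r.gln)
               for r in survey(rev, localize=False)}
        for key in fwd:
            assert fwd[key] == pytest.approx(bwd[key], abs=1e-9)

    def test_linked_set_monotone_in_threshold(self, planted_model):
        model, _ = planted_model
        sets = []
        for thr in (0.5, 0.7, 0.9, 1.1):
            recs = survey(model, threshold=thr, localize=False)
            sets.append({tuple(r.pair) for r in recs if r.linked})
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo


class TestHistogram:
    def test_counts_conserved_and_cumulative_reaches_one(self, planted_model):
        records = survey(planted_model[0], localize=False)
        edges, counts, cum, summary = gln_histogram(records)
        assert counts.sum() == len(records)
        assert cum[-1] == pytest.approx(1.0)
        assert summary["n_pairs"] == len(records)

    def test_all_zero_glns_single_bin(self, rng):
        chains = [random_open_chain(rng, 10, start=(500.0 * i, 0, 0))
                  for i in range(3)]
        records = survey(_model_of(chains), localize=False)
        edges, counts, cum, summary = gln_histogram(records, bin_width=0.1)
        assert counts[0] == len(records)
        assert cum[0] == pytest.approx(1.0)

    def test_planted_link_fraction_recovered(self):
        model, truth = make_toy_genome(10, 2, 60, seed=9)
        records = survey(model, localize=False)
        _, _, _, summary = gln_histogram(records)
        assert summary["fraction_linked"] == pytest.approx(
            len(truth) / len(records), abs=1e-9)


class TestMultiLinks:
    def _records(self, edges, nodes="abcd"):
        from chromolink.chain_io import LinkRecord
        recs = []
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                linked = (a, b) in edges or (b, a) in edges
                recs.append(LinkRecord(pair=(a, b),
                                       gln=1.0 if linked else 0.0,
                                       linked=linked))
        return recs

    def test_path_component_with_degrees(self):
        graph = multi_links(self._records({("a", "b"), ("b", "c")}))
        comps = graph.multiple_links
        assert len(comps) == 1
        assert comps[0]["chromosomes"] == ["a", "b", "c"]
        assert comps[0]["degrees"]["b"] == 2

    def test_no_edges_no_components(self):
        graph = multi_links(self._records(set()))
        assert graph.multiple_links == []

    def test_planted_four_chain_path(self):
        edges = {("a", "b"), ("b", "c"), ("c", "d")}
        comps = multi_links(self._records(edges)).multiple_links
        assert len(comps) == 1
        assert comps[0]["chromosomes"] == ["a", "b", "c", "d"]
        assert comps[0]["edges"] == [("a", "b"), ("b", "c"), ("c", "d")]

    def test_component_count_matches_union_find(self, rng):
        nodes = "abcdefgh"
        edges = set()
        for _ in range(6):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            edges.add((nodes[min(i, j)], nodes[max(i, j)]))
        graph = multi_links(self._records(edges, nodes))
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        sizes = {}
        for n in nodes:
            sizes.setdefault(find(n), set()).add(n)
        expected = sorted(tuple(sorted(s)) for s in sizes.values()
                          if len(s) >= 3)
        got = sorted(tuple(c["chromosomes"]) for c in graph.multiple_links)
        assert got == expected


class TestConservation:
    def _hopf_model(self, model_id, jitter_seed=None):
        a, b = (open_chain(c, 0.02) for c in hopf_pair(50, radius=2.0))
        chains = [a, b, Polyline(np.c_[np.linspace(0, 9, 20) + 60,
                                       np.zeros(20), np.zeros(20)])]
        return _model_of(chains, model=model_id)

    def test_identical_models_stable_pair(self):
        models = [self._hopf_model(str(i)) for i in range(10)]
        rep = conservation(models)
        assert rep.count("a", "b") == 10
        assert ("a", "b") in rep.stable_pairs

    def test_pair_linked_in_3_of_10_models_is_unstable(self, rng):
        linked = [self._hopf_model(str(i)) for i in range(3)]
        unlinked = []
        for i in range(3, 10):
            chains = [random_open_chain(rng, 30, start=(80.0 * k, 0, 0))
                      for k in range(3)]
            unlinked.append(_model_of(chains, model=str(i)))
        rep = conservation(linked + unlinked)
        assert rep.count("a", "b") == 3
        assert ("a", "b") not in rep.stable_pairs

    def test_unlinked_pair_has_count_zero(self):
        models = [self._hopf_model(str(i)) for i in range(3)]
        rep = conservation(models)
        assert rep.count("a", "c") == 0

    def test_name_mismatch_rejected(self, rng):
        m1 = _model_of([random_open_chain(rng, 10),
                        random_open_chain(rng, 10, start=(30, 0, 0))])
        m2 = GenomeModel("c", "2", [
            Chromosome("x", random_open_chain(rng, 10)),
            Chromosome("y", random_open_chain(rng, 10, start=(30, 0, 0)))])
        with pytest.raises(ValueError, match="names differ"):
            conservation([m1, m2])


class TestClosurePreservation:
    def test_worked_example_72_percent(self):
        assert closure_preservation_estimate(0.9, 0.8, 0.0) == \
            pytest.approx(0.72, abs=1e-12)

    def test_worked_example_40_5_percent(self):
        assert closure_preservation_estimate(0.9, 0.8, 0.25) == \
            pytest.approx(0.405, abs=1e-12)

    def test_identity_case(self):
        assert closure_preservation_estimate(1.0, 1.0, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            closure_preservation_estimate(1.2, 0.5, 0.0)
        with pytest.raises(ValueError):
            closure_preservation_estimate(0.5, 0.5, -0.1)
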