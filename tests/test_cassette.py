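"""Junction catalogue, spanning-read counting, architecture inference."""

import numpy as np
import pytest

from epspscnv import cassette as cas
from epspscnv import maplite as ml
from epspscnv import simulate as sim
from epspscnv.maplite import AlignmentRecord
from epspscnv.simulate import random_seq, revcomp


@pytest.fixture(scope="module")
def domains():
    rng = np.random.default_rng(77)
    return {"A": random_seq(rng, 3000), "B": random_seq(rng, 2500),
            "I": random_seq(rng, 500), "st": random_seq(rng, 451)}


class TestModel:
    def test_standard_layout_yields_canonical_junction_names(self, domains):
        model = cas.build_cassette_model(cas.standard_layout(
            domains["A"], domains["B"], domains["I"], domains["st"]))
        assert {nm for nm, _ in model.junctions} == \
            {"STs-A", "A-B", "B-I", "I-B", "B-ST", "INV"}
        # palindromic layout: two instances of each domain junction, one INV
        from collections import Counter
        counts = Counter(nm for nm, _ in model.junctions)
        assert counts["INV"] == 1
        assert all(counts[nm] == 2 for nm in cas.DOMAIN_JUNCTIONS)

    def test_single_domain_model_has_no_junctions(self, domains):
        model = cas.build_cassette_model([("A", "+", domains["A"])])
        assert model.junctions == []

    def test_boundaries_sum_to_total_length(self, domains):
        layout = cas.standard_layout(domains["A"], domains["B"], domains["I"],
                                     domains["st"])
        model = cas.build_cassette_model(layout)
        assert model.boundaries[-1] == len(model.sequence)
        assert len(model.sequence) == sum(len(s) for _, _, s in layout)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            cas.build_cassette_model([])

    def test_reverse_complement_junctions_pool_to_forward_names(self):
        assert cas.canonical_junction("B", "-", "I", "-") == "I-B"
        assert cas.canonical_junction("I", "-", "B", "-") == "B-I"
        assert cas.canonical_junction("B", "-", "A", "-") == "A-B"
        assert cas.canonical_junction("A", "-", "ST_large", "+") == "STs-A"
        assert cas.canonical_junction("ST_small", "+", "ST_small", "-") == "INV"


class TestCounting:
    def _rec(self, rid, start, stop, read_len=None):
        return AlignmentRecord(rid, "m", start, stop, "+",
                               [(start, 0, stop - start)], True,
                               read_length=read_len or (stop - start))

    def test_read_spanning_with_sufficient_anchor_counts(self):
        juncs = [("m", "A-B", 1000)]
        sup, = cas.count_junction_support([self._rec("r", 850, 1150)], juncs,
                                          min_anchor=100)
        assert sup.n_spanning == 1

    def test_read_terminating_at_junction_does_not_count(self):
        juncs = [("m", "A-B", 1000)]
        sup, = cas.count_junction_support([self._rec("r", 600, 1000)], juncs,
                                          min_anchor=100)
        assert sup.n_spanning == 0

    def test_anchor_shorter_than_minimum_does_not_count(self):
        juncs = [("m", "A-B", 1000)]
        sup, = cas.count_junction_support([self._rec("r", 950, 1500)], juncs,
                                          min_anchor=100)
        assert sup.n_spanning == 0

    def test_reads_avoiding_all_junctions_give_zero_support(self):
        juncs = [("m", nm, p) for nm, p in
                 [("STs-A", 100), ("A-B", 5000), ("INV", 9000)]]
        recs = [self._rec("r1", 200, 4000), self._rec("r2", 5200, 8800)]
        sups = cas.count_junction_support(recs, juncs, min_anchor=100)
        assert all(s.n_spanning == 0 for s in sups)

    def test_nonpositive_anchor_rejected(self):
        with pytest.raises(ValueError):
            cas.count_junction_support([], [("m", "A-B", 10)], min_anchor=0)

    def test_support_scales_with_coverage(self, small_pair):
        _, _, res, truth = small_pair
        idx = ml.build_index(res)
        juncs = [(ch, nm, p) for nm, ch, p in truth.junctions]
        counts = {}
        for cov in (10, 20):
            reads = sim.simulate_reads(res, "long", cov, seed=50)
            recs = ml.map_reads(reads, idx, seed=51)
            sups = cas.count_junction_support(recs, juncs, min_anchor=100)
            counts[cov] = sum(s.n_spanning for s in sups)
        ratio = counts[20] / counts[10]
        assert 1.6 <= ratio <= 2.4


class TestArchitecture:
    def _sup(self, mapping):
        return [cas.JunctionSupport(nm, 0, n) for nm, n in mapping.items()]

    def test_half_abundant_inversion_called_palindromic(self):
        counts = {"STs-A": 545, "A-B": 466, "B-I": 466, "I-B": 466,
                  "B-ST": 545, "INV": 265}
        assert cas.infer_architecture(self._sup(counts)) == "palindromic_tandem"

    def test_equal_inversion_support_called_simple_tandem(self):
        counts = {nm: 500 for nm in cas.DOMAIN_JUNCTIONS}
        counts["INV"] = 480
        assert cas.infer_architecture(self._sup(counts)) == "simple_tandem"

    def test_missing_domain_junction_is_unsupported(self):
        counts = {nm: 500 for nm in cas.DOMAIN_JUNCTIONS}
        counts["A-B"] = 0
        counts["INV"] = 250
        assert cas.infer_architecture(self._sup(counts)) == "unsupported"

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            cas.infer_architecture([])

    def test_simulated_simple_tandem_not_called_palindromic(self, domains):
        """A non-inverted tandem array supports every domain junction about
        equally and must not produce the half-abundance signature."""
        fusion = [("A", "+", domains["A"]), ("B", "+", domains["B"][:500]),
                  ("I", "+", domains["I"]), ("B", "+", domains["B"][500:])]
        st = ("ST_large", "+", domains["st"] * 10)
        genome_layout = [st] + fusion * 3 + [st]
        genome_model = cas.build_cassette_model(genome_layout)
        genome = sim.GenomeModel(sequences={"T": genome_model.sequence},
                                 name="tandem")
        reads = sim.simulate_reads(genome, "long", 25,
                                   length_params={"median": 4000}, seed=61)
        # count against the single-unit model
        unit_model = cas.build_cassette_model([st] + fusion + [st])
        idx = ml.build_index({"model": unit_model.sequence})
        recs = ml.map_reads(reads, idx, seed=62)
        sups = cas.count_junction_support(
            recs, [("model", nm, p) for nm, p in unit_model.junctions],
            min_anchor=100)
        call = cas.infer_architecture(sups)
        assert call == "simple_tandem"


class TestAlternatives:
    def test_reads_pick_the_true_candidate(self, domains):
        rng = np.random.default_rng(91)
        X, Y, Z = (random_seq(rng, 3000) for _ in range(3))
        cand1, cand2 = X + Y, X + Z
        genome = sim.GenomeModel(sequences={"c1": cand1}, name="truthy")
        reads = sim.simulate_reads(genome, "long", 20,
                                   length_params={"median": 1500}, seed=92)
        rep = cas.validate_alternatives({"one": (cand1, 3000),
                                         "two": (cand2, 3000)}, reads)
        assert rep["winner"] == "one"
        assert rep["one"]["spanning"] > 5 * max(rep["two"]["spanning"], 1)

    def test_identical_candidates_are_inconclusive(self, domains):
        rng = np.random.default_rng(93)
        seq = random_seq(rng, 4000)
        genome = sim.GenomeModel(sequences={"c": seq}, name="g")
        reads = sim.simulate_reads(genome, "long", 10,
                                   length_params={"median": 1500}, seed=94)
        rep = cas.validate_alternatives({"a": (seq, 2000), "b": (seq, 2000)}, reads)
        assert rep["winner"] is None
        assert rep["a"]["spanning"] == rep["b"]["spanning"]

    def test_zero_reads_inconclusive_and_empty_candidates_rejected(self, domains):
        rep = cas.validate_alternatives({"a": (domains["A"], 100),
                                         "b": (domains["B"], 100)}, [])
        assert rep["winner"] is None
        with pytest.raises(ValueError):
            cas.validate_alternatives({}, [])


class TestDotplot:
    def test_inverted_repeat_appears_as_antidiagonal_chain(self):
        rng = np.random.default_rng(101)
        u = random_seq(rng, 400)
        seq = random_seq(rng, 1000) + u + random_seq(rng, 800) + revcomp(u)
        segs = [s for s in cas.self_dotplot(seq, k=15) if s[3] == "-"]
        big = max(segs, key=lambda s: s[2])
        assert big[2] >= 390
        assert abs(big[0] - 1000) <= 10 and abs(big[1] - 2200) <= 10

    def test_tandem_array_matches_at_unit_offsets(self):
        rng = np.random.default_rng(103)
        u = random_seq(rng, 200)
        seq = u * 5
        segs = [s for s in cas.self_dotplot(seq, k=15) if s[3] == "+"]
        offsets = {s[1] - s[0] for s in segs}
        assert offsets and all(off % 200 == 0 for off in offsets)

    def test_random_sequences_have_almost_no_offdiagonal_matches(self):
        # expected chance matches per sequence ~ L^2 / 4^k ~ 0.1 << 1
        rng = np.random.default_rng(105)
        total = sum(len(cas.self_dotplot(random_seq(rng, 10_000), k=15))
                    for _ in range(3))
        assert total <= 2

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            cas.self_dotplot("ACGT", k=15)
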