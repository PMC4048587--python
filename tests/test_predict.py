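"""Relevant-hypothesis search, local kNN prediction and the overall call."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sohn import (
    Label,
    PredictConfig,
    build_sohn,
    find_relevant_hypotheses,
    global_predict,
    local_predict,
    parse_molecule,
    predict,
)
from sohn.predict import LocalPrediction

from conftest import SetHypothesis


def relevant_oracle(net, query):
    """Brute force: eligible = match + domain; keep hypotheses with no
    eligible hypothesis of strictly smaller coverage."""
    eligible = {
        n for n in net.node_ids()
        if net.hypothesis(n).matches(query) and net.hypothesis(n).in_domain(query)
    }
    return sorted(
        h for h in eligible
        if not any(
            net.coverage_of(z) < net.coverage_of(h) for z in eligible if z != h
        )
    )


class TestFindRelevantHypotheses:
    def test_matches_oracle_on_random_networks(self, tiny_dataset):
        rng = random.Random(4)
        all_canons = [e.molecule.canonical_form for e in tiny_dataset]
        for _ in range(20):
            hyps = []
            for i in range(rng.randint(2, 12)):
                scope = rng.sample(all_canons, rng.randint(1, 25))
                # some hypotheses have a restricted applicability domain
                domain = (
                    None if rng.random() < 0.7
                    else rng.sample(all_canons, rng.randint(5, 30))
                )
                hyps.append(SetHypothesis(f"f{i}", scope, domain))
            net = build_sohn(hyps, tiny_dataset)
            query = tiny_dataset.examples[
                rng.randrange(len(tiny_dataset))
            ].molecule
            assert find_relevant_hypotheses(net, query) == relevant_oracle(
                net, query
            )

    def test_query_matching_nothing_falls_back_to_root(self, small_network):
        query = parse_molecule("C#CC#CC#C")  # triyne: far outside the grammar
        relevant = find_relevant_hypotheses(small_network, query)
        assert relevant == ["h0"]

    def test_exact_match_returns_the_example_node(self, small_dataset,
                                                  small_network):
        example = small_dataset.examples[0]
        query = parse_molecule(example.molecule.canonical_form, "query")
        relevant = find_relevant_hypotheses(small_network, query)
        assert len(relevant) == 1
        hyp = small_network.hypothesis(relevant[0])
        assert hyp.kind == "EXAMPLE"
        assert hyp.example.molecule.canonical_form == example.molecule.canonical_form

    def test_chain_returns_most_specific_and_independent_branches(
        self, tiny_dataset
    ):
        """A matching chain h1 > h6 yields only h6; an independent matching
        branch h7 is reported alongside it."""
        canons = sorted({e.molecule.canonical_form for e in tiny_dataset})
        novel = "CCCCCCCCCCCC"  # query structure absent from the dataset
        assert novel not in canons
        h1 = SetHypothesis("h1", set(canons[:10]) | {novel})
        h6 = SetHypothesis("h6", set(canons[:4]) | {novel})       # inside h1
        h7 = SetHypothesis("h7", set(canons[12:20]) | {novel})    # independent
        net = build_sohn([h1, h6, h7], tiny_dataset)
        query = parse_molecule(novel, "q")
        assert find_relevant_hypotheses(net, query) == ["h6", "h7"]


class TestLocalPrediction:
    def test_exact_match_gives_certain_prediction(self, small_dataset,
                                                  small_network):
        example = small_dataset.examples[0]
        query = parse_molecule(example.molecule.canonical_form, "q")
        node = find_relevant_hypotheses(small_network, query)[0]
        lp = local_predict(small_network.hypothesis(node), query, small_dataset)
        assert lp.confidence == 1.0
        assert lp.predicted_class is example.label
        assert lp.signal == example.instance_signal

    def test_worked_example_two_neighbours(self, tiny_dataset):
        """Similarities {0.81, 0.25}, signals {+1, -1}, k=2:
        weights {0.9, 0.5}, S = (0.9 - 0.5)/2 = 0.2."""
        canons = [e.molecule.canonical_form for e in tiny_dataset]
        unique = [e for e in tiny_dataset
                  if canons.count(e.molecule.canonical_form) == 1]
        pos = next(e for e in unique if e.label is Label.POSITIVE)
        neg = next(e for e in unique if e.label is Label.NEGATIVE)

        class TwoNeighbourHyp(SetHypothesis):
            def __init__(self):
                super().__init__(
                    "h", {pos.molecule.canonical_form, neg.molecule.canonical_form}
                )

            def similarity(self, s1, s2):
                target = s2 if s1.id == "query" else s1
                return 0.81 if target.id == pos.id else 0.25

        query = parse_molecule("c1ccccc1", "query")
        lp = local_predict(TwoNeighbourHyp(), query, tiny_dataset, k=2)
        assert lp.k_used == 2
        assert lp.signal == pytest.approx(0.2, abs=1e-12)
        assert lp.predicted_class is Label.POSITIVE
        assert lp.confidence == pytest.approx(0.2, abs=1e-12)
        # Eq. 2: ws = (0.9 - 0.5)/(0.9 + 0.5)
        assert lp.weighted_signal == pytest.approx(0.4 / 1.4, abs=1e-12)

    def test_unanimous_identical_neighbours_reach_signal_one(self, tiny_dataset):
        pos_examples = [e for e in tiny_dataset if e.label is Label.POSITIVE][:3]

        class UnanimousHyp(SetHypothesis):
            def similarity(self, s1, s2):
                return 1.0

        hyp = UnanimousHyp("h", {e.molecule.canonical_form for e in pos_examples})
        query = parse_molecule("c1ccccc1", "q")
        k = hyp.coverage(tiny_dataset).N
        lp = local_predict(hyp, query, tiny_dataset, k=k)
        assert lp.signal == pytest.approx(1.0)

    def test_thin_support_shrinks_signal_toward_zero(self, tiny_dataset):
        """With k_used < k the divisor stays k, moderating the signal."""
        pos = next(e for e in tiny_dataset if e.label is Label.POSITIVE)

        class OneNeighbourHyp(SetHypothesis):
            def similarity(self, s1, s2):
                return 1.0

        hyp = OneNeighbourHyp("h", {pos.molecule.canonical_form})
        query = parse_molecule("c1ccccc1", "q")
        lp = local_predict(hyp, query, tiny_dataset, k=10)
        n_identical = hyp.coverage(tiny_dataset).N
        assert lp.signal == pytest.approx(n_identical / 10)
        lp_full = local_predict(hyp, query, tiny_dataset, k=10,
                                divide_by_k_used=True)
        assert abs(lp_full.signal) >= abs(lp.signal)

    def test_overruled_flag_set_on_contradiction(self, tiny_dataset):
        pos_ids = [e for e in tiny_dataset if e.label is Label.POSITIVE]
        neg_ids = [e for e in tiny_dataset if e.label is Label.NEGATIVE]
        if len(pos_ids) < 2 or len(neg_ids) < 1:
            pytest.skip("fixture lacks class diversity")

        class Wrapper(SetHypothesis):
            # nearest neighbour is the lone negative supporter
            def similarity(self, s1, s2):
                target = s2 if s1.id == "q" else s1
                neg_canons = {e.molecule.canonical_form for e in neg_ids}
                return 0.95 if target.canonical_form in neg_canons else 0.05

        scope = {e.molecule.canonical_form for e in pos_ids[:4] + neg_ids[:1]}
        hyp = Wrapper("h", scope)
        stats = hyp.coverage(tiny_dataset)
        assert stats.signal() > 0  # reference signal says positive
        lp = local_predict(hyp, parse_molecule("c1ccccc1", "q"), tiny_dataset, k=1)
        assert lp.predicted_class is Label.NEGATIVE
        assert lp.overruled

    @given(
        sims=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        signs=st.lists(st.sampled_from([-1, 1]), min_size=10, max_size=10),
        k=st.integers(1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_moderated_and_expanded_forms_agree(self, sims, signs, k):
        """ws * (sum w)/k == (sum w*s)/k for random neighbour sets."""
        sims = sims[:k]
        weights = [math.sqrt(s) for s in sims]
        signal_sum = sum(w * s for w, s in zip(weights, signs))
        weight_sum = sum(weights)
        direct = signal_sum / k
        if weight_sum > 0:
            moderated = (signal_sum / weight_sum) * (weight_sum / k)
            assert abs(direct - moderated) < 1e-12
        assert abs(direct) <= 1.0 + 1e-12
        if weights:
            assert direct <= max(weights) + 1e-12


class TestGlobalPrediction:
    def _lp(self, signal):
        cls = (Label.POSITIVE if signal > 0
               else Label.NEGATIVE if signal < 0 else None)
        return LocalPrediction("h", [], 0, signal, signal, cls,
                               abs(signal), False)

    def test_single_local_passes_through(self):
        gp = global_predict([self._lp(0.6)])
        assert gp.overall_signal == pytest.approx(0.6)
        assert gp.predicted_class is Label.POSITIVE

    def test_worked_example_confidence_weighting(self):
        """(0.6*0.6 - 0.2*0.2)/(0.6 + 0.2) = 0.4."""
        gp = global_predict([self._lp(0.6), self._lp(-0.2)])
        assert gp.overall_signal == pytest.approx(0.4, abs=1e-12)
        assert gp.predicted_class is Label.POSITIVE
        assert gp.raw_confidence == pytest.approx(0.4, abs=1e-12)

    def test_band_parameter_makes_call_equivocal(self):
        gp = global_predict([self._lp(0.6), self._lp(-0.2)], a=0.0, b=0.5)
        assert gp.predicted_class is None

    def test_all_zero_confidence_is_equivocal(self):
        gp = global_predict([self._lp(0.0), self._lp(0.0)])
        assert gp.predicted_class is None
        assert gp.overall_signal == 0.0

    def test_overruled_locals_dropped_on_request(self):
        overruled = LocalPrediction("h", [], 0, -0.8, -0.8, Label.NEGATIVE,
                                    0.8, True)
        keep = global_predict([self._lp(0.3), overruled])
        drop = global_predict([self._lp(0.3), overruled], ignore_overruled=True)
        assert keep.overall_signal < 0 < drop.overall_signal

    def test_empty_local_list_raises(self):
        with pytest.raises(ValueError):
            global_predict([])

    @given(
        signals=st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=8),
        b1=st.floats(0.0, 1.0),
        b2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_raising_b_never_unmakes_equivocal(self, signals, b1, b2):
        locals_ = [self._lp(s) for s in signals]
        lo, hi = sorted([b1, b2])
        call_lo = global_predict(locals_, b=lo).predicted_class
        call_hi = global_predict(locals_, b=hi).predicted_class
        if call_lo is None:
            assert call_hi is None


class TestEndToEnd:
    def test_training_structure_predicts_its_own_label(self, small_dataset,
                                                       small_network):
        example = small_dataset.examples[3]
        query = parse_molecule(example.molecule.canonical_form, "q")
        result = predict(small_network, query)
        duplicates = [
            e for e in small_dataset
            if e.molecule.canonical_form == example.molecule.canonical_form
        ]
        if len({e.label for e in duplicates}) == 1:
            assert result.predicted_class is example.label
            assert result.raw_confidence == 1.0

    def test_prediction_attaches_paths_and_support(self, small_dataset,
                                                   small_network):
        query = parse_molecule("O=[N+]([O-])c1ccc(CC)cc1", "q")
        result = predict(small_network, query)
        assert result.m >= 1
        for lp in result.locals:
            assert lp.neighbours
            paths = result.sar_paths[lp.hypothesis_id]
            assert paths
            for path in paths:
                assert path.node_ids[0] == "h0"
                assert path.node_ids[-1] == lp.hypothesis_id

    def test_small_hypothesis_counts_on_reference_queries(self, small_dataset,
                                                          small_network):
        ms = []
        for example in small_dataset.examples[:30]:
            query = parse_molecule(example.molecule.canonical_form, "q")
            ms.append(predict(small_network, query).m)
        assert max(ms) <= 6
        assert sum(m <= 4 for m in ms) / len(ms) >= 0.9
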