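"""Descriptor matrix, information gain, tree growth and hypothesis emission."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sohn import (
    Label,
    MiningConfig,
    build_descriptor_matrix,
    filter_hypotheses,
    generate_synthetic_dataset,
    grow_tree,
    information_gain,
    mine_hypotheses,
    tree_to_hypotheses,
)


def entropy_oracle(labels):
    """Independent Shannon entropy implementation."""
    n = len(labels)
    h = 0.0
    for value in set(labels):
        p = labels.count(value) / n
        h -= p * math.log2(p)
    return h


def gain_oracle(labels, split):
    parent = entropy_oracle(labels)
    left = [l for l, s in zip(labels, split) if s]
    right = [l for l, s in zip(labels, split) if not s]
    child = 0.0
    for branch in (left, right):
        if branch:
            child += len(branch) / len(labels) * entropy_oracle(branch)
    return parent - child


class TestInformationGain:
    def test_perfect_split_of_balanced_labels_is_one_bit(self):
        labels = [True] * 4 + [False] * 4
        split = [True] * 4 + [False] * 4
        assert information_gain(labels, split) == pytest.approx(1.0)

    def test_proportional_split_has_zero_gain(self):
        labels = [True, True, False, False] * 2
        split = [True, True, True, True, False, False, False, False]
        # each child keeps the 50/50 parent ratio
        assert information_gain(labels, split) == pytest.approx(0.0)

    def test_recomputation_is_stable(self):
        labels = [True] * 4 + [False] * 4
        split = [True] * 4 + [False] * 4
        assert information_gain(labels, split) == information_gain(labels, split)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, rows):
        labels = [l for l, _ in rows]
        split = [s for _, s in rows]
        assert information_gain(labels, split) == pytest.approx(
            gain_oracle(labels, split)
        )


def toy_matrix(columns: dict[str, list[bool]], labels: list[Label]):
    index = [f"e{i}" for i in range(len(labels))]
    matrix = pd.DataFrame(columns, index=index, dtype=bool)
    return matrix, dict(zip(index, labels))


P, N = Label.POSITIVE, Label.NEGATIVE


class TestDescriptorMatrix:
    def test_columns_are_non_rare_sorted_keys(self, small_dataset, small_dictionary):
        matrix = build_descriptor_matrix(small_dataset, small_dictionary)
        assert list(matrix.columns) == small_dictionary.non_rare_keys()
        assert list(matrix.index) == small_dataset.ids
        rare = [k for k in small_dictionary.fragments
                if not small_dictionary.non_rare(k)]
        assert not set(rare) & set(matrix.columns)

    def test_presence_agrees_with_substructure_match(self, small_dataset,
                                                     small_dictionary):
        matrix = build_descriptor_matrix(small_dataset, small_dictionary)
        sample_keys = list(matrix.columns)[::40]
        for key in sample_keys:
            frag = small_dictionary.fragments[key]
            for e in small_dataset.examples[:25]:
                assert matrix.at[e.id, key] == frag.matches(e.molecule)

    def test_rebuild_is_identical(self, small_dataset, small_dictionary):
        a = build_descriptor_matrix(small_dataset, small_dictionary)
        b = build_descriptor_matrix(small_dataset, small_dictionary)
        pd.testing.assert_frame_equal(a, b)


class TestTree:
    def test_single_separating_fragment_gives_depth_one_tree(self):
        matrix, labels = toy_matrix(
            {"f": [True] * 4 + [False] * 4}, [P] * 4 + [N] * 4
        )
        tree = grow_tree(matrix, labels)
        assert tree.split_fragment == "f"
        assert tree.present_branch.is_leaf and tree.absent_branch.is_leaf

    def test_pure_node_is_a_leaf(self):
        matrix, labels = toy_matrix({"f": [True, False] * 3}, [P] * 6)
        assert grow_tree(matrix, labels).is_leaf

    def test_equal_gain_tie_breaks_lexicographically(self):
        col = [True] * 4 + [False] * 4
        matrix, labels = toy_matrix({"zeta": col, "alpha": col}, [P] * 4 + [N] * 4)
        assert grow_tree(matrix, labels).split_fragment == "alpha"

    def test_min_node_size_stops_splitting(self):
        matrix, labels = toy_matrix({"f": [True, False, True]}, [P, N, N])
        tree = grow_tree(matrix, labels, MiningConfig(min_node_size=4))
        assert tree.is_leaf

    def test_child_example_sets_partition_parent(self, small_dataset,
                                                 small_dictionary):
        matrix = build_descriptor_matrix(small_dataset, small_dictionary)
        labels = {e.id: e.label for e in small_dataset}
        tree = grow_tree(matrix, labels)
        for node in tree.walk():
            if not node.is_leaf:
                left = set(node.present_branch.example_ids)
                right = set(node.absent_branch.example_ids)
                assert left | right == set(node.example_ids)
                assert not left & right

    def test_identical_inputs_give_identical_trees(self, small_dataset,
                                                   small_dictionary):
        matrix = build_descriptor_matrix(small_dataset, small_dictionary)
        labels = {e.id: e.label for e in small_dataset}
        assert (
            grow_tree(matrix, labels).structure_hash()
            == grow_tree(matrix, labels).structure_hash()
        )


class TestHypothesisEmission:
    def test_depth_one_tree_emits_single_fragment_hypothesis(
        self, small_dictionary
    ):
        key = small_dictionary.non_rare_keys()[0]
        matrix, labels = toy_matrix({key: [True] * 4 + [False] * 4},
                                    [P] * 4 + [N] * 4)
        tree = grow_tree(matrix, labels)
        hyps = tree_to_hypotheses(tree, small_dictionary)
        assert len(hyps) == 1
        assert hyps[0].fragment_keys == (key,)

    def test_path_conjunctions_nest_coverage(self, small_dataset,
                                             small_dictionary):
        hyps = tree_to_hypotheses(
            grow_tree(
                build_descriptor_matrix(small_dataset, small_dictionary),
                {e.id: e.label for e in small_dataset},
            ),
            small_dictionary,
        )
        by_keys = {frozenset(h.fragment_keys): h for h in hyps}
        for keys_a, hyp_a in by_keys.items():
            for keys_b, hyp_b in by_keys.items():
                if keys_a < keys_b:  # b extends a's conjunction
                    assert (
                        hyp_b.coverage(small_dataset).coverage
                        <= hyp_a.coverage(small_dataset).coverage
                    )

    def test_absence_only_paths_emit_nothing(self, small_dictionary):
        keys = small_dictionary.non_rare_keys()[:2]
        # second split only separates classes inside the absence branch
        matrix, labels = toy_matrix(
            {
                keys[0]: [True] * 4 + [False] * 8,
                keys[1]: [False] * 4 + [True] * 4 + [False] * 4,
            },
            [P] * 4 + [P] * 4 + [N] * 4,
        )
        tree = grow_tree(matrix, labels)
        hyps = tree_to_hypotheses(tree, small_dictionary)
        emitted = {h.fragment_keys for h in hyps}
        # the hypothesis from the absence branch is {keys[1]}, not a pair
        assert all(len(k) == 1 for k in emitted)

    def test_node_mode_emits_last_fragment_only(self, small_dataset,
                                                small_dictionary):
        tree = grow_tree(
            build_descriptor_matrix(small_dataset, small_dictionary),
            {e.id: e.label for e in small_dataset},
        )
        node_hyps = tree_to_hypotheses(tree, small_dictionary, emit_mode="node")
        assert all(len(h.fragment_keys) == 1 for h in node_hyps)


class TestFiltering:
    def test_coverage_and_signal_thresholds(self, small_dataset,
                                            small_dictionary):
        hyps = tree_to_hypotheses(
            grow_tree(
                build_descriptor_matrix(small_dataset, small_dictionary),
                {e.id: e.label for e in small_dataset},
            ),
            small_dictionary,
        )
        kept = filter_hypotheses(hyps, small_dataset, min_coverage=4,
                                 min_abs_signal=0.3)
        for hyp in kept:
            stats = hyp.coverage(small_dataset)
            assert stats.N >= 4
            assert abs(stats.signal()) >= 0.3
        # thresholds actually bite relative to the unfiltered list
        assert len(kept) < len(hyps)

    def test_duplicate_scopes_keep_shortest_description(self, small_dataset,
                                                        small_dictionary):
        kept = filter_hypotheses(
            tree_to_hypotheses(
                grow_tree(
                    build_descriptor_matrix(small_dataset, small_dictionary),
                    {e.id: e.label for e in small_dataset},
                ),
                small_dictionary,
            ),
            small_dataset,
        )
        coverages = [h.coverage(small_dataset).coverage for h in kept]
        assert len(coverages) == len(set(coverages))


class TestPlantedRuleRecovery:
    def test_nitro_alert_recovered_at_small_scale(self):
        d = generate_synthetic_dataset(150, seed=7, noise=0.0)
        from sohn import build_fragment_dictionary

        dictionary = build_fragment_dictionary(d)
        hyps = mine_hypotheses(d, dictionary)
        nitro = [
            h for h in hyps
            if any("[N+](=O)[O-]" in k for k in h.fragment_keys)
        ]
        assert nitro, "no nitro-containing hypothesis mined"
        best = max(nitro, key=lambda h: h.coverage(d).N)
        assert best.signal(d) > 0.8  # noise-free planted rule
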