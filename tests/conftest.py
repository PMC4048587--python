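"""Shared fixtures: small seeded datasets, trained artifacts, and synthetic
hypotheses with arbitrary coverage for order-theory oracle tests."""

from __future__ import annotations

import pytest

from sohn import (
    Hypothesis,
    HypothesisStats,
    Label,
    build_fragment_dictionary,
    build_sohn,
    generate_synthetic_dataset,
    mine_hypotheses,
)


class SetHypothesis(Hypothesis):
    """A hypothesis whose scope is an explicit set of canonical forms.

    Lets tests plant arbitrary coverage/scope/domain configurations and
    check the network and search algorithms against brute-force oracles.
    """

    kind = "STRUCTURAL"

    def __init__(self, hyp_id: str, scope_canons, in_domain_canons=None):
        super().__init__(hyp_id)
        self.scope = frozenset(scope_canons)
        self.domain = None if in_domain_canons is None else frozenset(in_domain_canons)

    def matches(self, mol):
        return mol.canonical_form in self.scope

    def in_domain(self, mol):
        return self.domain is None or mol.canonical_form in self.domain

    def similarity(self, s1, s2):
        return 1.0 if s1.canonical_form == s2.canonical_form else 0.5


def brute_force_hasse(coverages: dict[str, frozenset]) -> set[tuple[str, str]]:
    """Independent oracle: transitive reduction of the strict-subset order."""
    edges = set()
    for u, cu in coverages.items():
        for v, cv in coverages.items():
            if cv < cu and not any(
                cv < cz < cu for n, cz in coverages.items() if n not in (u, v)
            ):
                edges.add((u, v))
    return edges


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 seeded molecules, noise-free labels."""
    return generate_synthetic_dataset(30, seed=3, noise=0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """150 seeded molecules with 5% label noise."""
    return generate_synthetic_dataset(150, seed=7, noise=0.05)


@pytest.fixture(scope="session")
def small_dictionary(small_dataset):
    return build_fragment_dictionary(small_dataset)


@pytest.fixture(scope="session")
def small_hypotheses(small_dataset, small_dictionary):
    return mine_hypotheses(small_dataset, small_dictionary)


@pytest.fixture(scope="session")
def small_network(small_hypotheses, small_dataset, small_dictionary):
    return build_sohn(small_hypotheses, small_dataset, small_dictionary)
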