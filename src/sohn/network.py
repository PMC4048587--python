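"""The self-organising hypothesis network (SOHN).

Hypotheses are organised by the *generalisation order*: h1 is more general
than h2 iff, relative to a fixed reference dataset, the coverage of h2 is a
strict subset of the coverage of h1.  Hypotheses with identical coverage are
incomparable siblings.  The network stores the transitive reduction of this
strict partial order (the Hasse diagram), so the edge set is independent of
insertion order: the universal root sits at the top, example hypotheses (one
node per distinct structure) at the bottom, and every edge means "direct
parent is more general than direct child".

The structure is a DAG, not a tree — a specific hypothesis may have several
more generic parents.  Paths from the root to a hypothesis read as SAR
routes: each step refines the scope, and the per-step signal contrast
highlights activity changes (e.g. a mitigating refinement flipping the sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chemio import Label, LabeledExample, ReferenceDataset
from .fragmentation import FragmentDictionary
from .hypotheses import (
    ExampleHypothesis,
    Hypothesis,
    HypothesisStats,
    RootHypothesis,
)

ROOT_ID = "h0"


class InsertionError(ValueError):
    """Raised when a hypothesis cannot enter the network."""


def is_more_general(h1: Hypothesis, h2: Hypothesis, dataset: ReferenceDataset) -> bool:
    """True iff coverage(h2, D) is a *strict* subset of coverage(h1, D).

    Identical coverages are incomparable (no parent/child relationship), as
    are overlapping-but-not-nested coverages.
    """
    c1 = h1.coverage(dataset).coverage
    c2 = h2.coverage(dataset).coverage
    return c2 < c1


@dataclass(frozen=True)
class SARPath:
    """A root-to-hypothesis path with per-step signal contrasts."""

    node_ids: tuple[str, ...]
    signal_contrasts: tuple[float, ...]  # child signal minus parent signal


class SOHNNetwork:
    """DAG of hypotheses under the coverage-based generalisation order.

    Created with a reference dataset, the network always contains the root
    hypothesis and one example hypothesis per distinct structure (duplicate
    structures collapse into a single node — they are indistinguishable to
    every hypothesis contract clause).  Additional hypotheses are added with
    :meth:`insert`.
    """

    def __init__(self, reference: ReferenceDataset,
                 dictionary: FragmentDictionary | None = None):
        self.reference = reference
        self.dictionary = dictionary
        self.graph = nx.DiGraph()
        self._coverage: dict[str, frozenset[str]] = {}
        root = RootHypothesis(ROOT_ID)
        self.graph.add_node(ROOT_ID, hypothesis=root)
        self._coverage[ROOT_ID] = frozenset(reference.ids)
        # one example node per distinct canonical structure
        by_canon: dict[str, list[LabeledExample]] = {}
        for example in reference:
            by_canon.setdefault(example.molecule.canonical_form, []).append(example)
        for canon, group in sorted(by_canon.items()):
            hyp = ExampleHypothesis(group[0])
            self._add_node(hyp)

    # -- basic access ------------------------------------------------------
    @property
    def root(self) -> RootHypothesis:
        return self.graph.nodes[ROOT_ID]["hypothesis"]

    def hypothesis(self, node_id: str) -> Hypothesis:
        return self.graph.nodes[node_id]["hypothesis"]

    def coverage_of(self, node_id: str) -> frozenset[str]:
        return self._coverage[node_id]

    def stats_of(self, node_id: str) -> HypothesisStats:
        return self.hypothesis(node_id).coverage(self.reference)

    def signal_of(self, node_id: str, y: Label = Label.POSITIVE) -> float:
        return self.stats_of(node_id).signal(y)

    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    # -- maintenance -------------------------------------------------------
    def _add_node(self, hyp: Hypothesis) -> str:
        """Link a hypothesis below its immediate predecessors and above its
        immediate successors, restoring the transitive reduction."""
        if hyp.id in self.graph:
            raise InsertionError(f"node id {hyp.id!r} already present")
        cov = hyp.coverage(self.reference).coverage
        if not cov:
            raise InsertionError(f"hypothesis {hyp.id!r} has empty coverage")
        supersets = [n for n, c in self._coverage.items() if cov < c]
        subsets = [n for n, c in self._coverage.items() if self._coverage[n] < cov]
        # immediate parents: minimal supersets; immediate children: maximal subsets
        parents = [
            u for u in supersets
            if not any(self._coverage[w] < self._coverage[u] for w in supersets)
        ]
        children = [
            v for v in subsets
            if not any(self._coverage[v] < self._coverage[w] for w in subsets)
        ]
        self.graph.add_node(hyp.id, hypothesis=hyp)
        self._coverage[hyp.id] = cov
        for u in parents:
            # an existing u->c edge with c below the new node is now transitive
            for c in children:
                if self.graph.has_edge(u, c):
                    self.graph.remove_edge(u, c)
            self.graph.add_edge(u, hyp.id)
        for v in children:
            self.graph.add_edge(hyp.id, v)
        return hyp.id

    def insert(self, hyp: Hypothesis) -> str:
        """Insert a hypothesis; empty coverage is rejected with a reason.

        A hypothesis whose coverage equals an existing node's becomes a
        sibling with the same parents and children but no edge between the
        two (identical coverages are incomparable)."""
        if self.dictionary is not None and getattr(hyp, "dictionary", None) is None \
                and hasattr(hyp, "fragments"):
            hyp.dictionary = self.dictionary
        return self._add_node(hyp)

    def remove(self, node_id: str) -> None:
        """Remove a mined hypothesis, re-establishing grandparent-grandchild
        edges where the order requires them."""
        if node_id not in self.graph:
            raise KeyError(f"node {node_id!r} not in network")
        hyp = self.hypothesis(node_id)
        if hyp.kind == "ROOT":
            raise ValueError("cannot remove the root hypothesis")
        if hyp.kind == "EXAMPLE":
            raise ValueError("cannot remove an example hypothesis")
        parents = list(self.graph.predecessors(node_id))
        children = list(self.graph.successors(node_id))
        self.graph.remove_node(node_id)
        del self._coverage[node_id]
        for u in parents:
            cu = self._coverage[u]
            for v in children:
                cv = self._coverage[v]
                if not cv < cu or self.graph.has_edge(u, v):
                    continue
                # add u->v unless some remaining node sits strictly between
                between = any(
                    cv < cz < cu
                    for n, cz in self._coverage.items()
                    if n not in (u, v)
                )
                if not between:
                    self.graph.add_edge(u, v)

    # -- analysis ----------------------------------------------------------
    def sar_paths(self, node_id: str) -> list[SARPath]:
        """All simple root-to-node paths with per-edge signal contrasts."""
        if node_id not in self.graph:
            raise KeyError(f"node {node_id!r} not in network")
        paths = []
        if node_id == ROOT_ID:
            return [SARPath((ROOT_ID,), ())]
        for path in nx.all_simple_paths(self.graph, ROOT_ID, node_id):
            contrasts = tuple(
                self.signal_of(child) - self.signal_of(parent)
                for parent, child in zip(path, path[1:])
            )
            paths.append(SARPath(tuple(path), contrasts))
        return paths

    def export_dot(self, max_label_len: int = 40) -> str:
        """Serialise to DOT.  Node fill encodes signal sign and intensity
        (green positive, red negative, saturation monotone in |signal|);
        example hypotheses are boxes ("closed structures"), the rest ovals.
        """
        lines = ["digraph SOHN {", "  rankdir=TB;"]
        for node_id in self.graph.nodes:
            hyp = self.hypothesis(node_id)
            signal = self.signal_of(node_id)
            intensity = int(round(255 * (1 - abs(signal))))
            if signal >= 0:
                colour = f"#{intensity:02x}ff{intensity:02x}"  # toward green
            else:
                colour = f"#ff{intensity:02x}{intensity:02x}"  # toward red
            label = hyp.human_description[:max_label_len].replace('"', "'")
            shape = "box" if hyp.kind == "EXAMPLE" else "ellipse"
            lines.append(
                f'  "{node_id}" [label="{label}", shape={shape}, '
                f'style=filled, fillcolor="{colour}", signal="{signal:+.3f}"];'
            )
        for u, v in sorted(self.graph.edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


def build_sohn(
    hypotheses: list[Hypothesis],
    reference: ReferenceDataset,
    dictionary: FragmentDictionary | None = None,
) -> SOHNNetwork:
    """Organise hypotheses plus the reference examples into a SOHN.

    Hypotheses with empty coverage are skipped (their signal is undefined).
    The resulting edge set is the Hasse diagram of the coverage order and is
    identical for any insertion order.
    """
    net = SOHNNetwork(reference, dictionary)
    for hyp in hypotheses:
        try:
            net.insert(hyp)
        except InsertionError:
            continue
    return net
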