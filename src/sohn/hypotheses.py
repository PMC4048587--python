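"""The hypothesis contract and its derived coverage/signal statistics.

A hypothesis is an interpretable knowledge unit that must implement three
clauses:

1. *scope match* — does it apply to a structure?
2. *domain match* — can it be reliably evaluated for a structure?
3. *similarity* — a symmetric index in [0, 1] between two structures.

Four kinds are provided: the universal root, structural hypotheses
(conjunctions of fragments that must all be present), property-range
hypotheses on a computed molecular property, and example hypotheses (a
single observed data point, maximally specific).

Relative to a reference dataset D, each hypothesis has a *coverage*
C(h, D) — the covered example ids — and a per-class *signal*

    S_y(h, D) = (L * n_y - N) / ((L - 1) * N)

measuring how far the class distribution among the covered examples deviates
from balance: 1 means the coverage is pure class y, 0 means y is at its
balanced share.  For two classes S_pos = -S_neg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from rdkit.Chem import Crippen, Descriptors

from .chemio import Label, LabeledExample, Molecule, ReferenceDataset
from .fragmentation import Fragment, FragmentDictionary, in_structural_domain


class EmptyCoverageError(ValueError):
    """Signal is undefined for a hypothesis covering no examples."""


@dataclass(frozen=True)
class HypothesisStats:
    """Coverage and signal of a hypothesis over a reference dataset."""

    coverage: frozenset[str]
    n_pos: int
    n_neg: int

    @property
    def N(self) -> int:
        return self.n_pos + self.n_neg

    def signal(self, y: Label = Label.POSITIVE) -> float:
        """S_y = (L*n_y - N)/((L-1)*N); binary: (2*n_y - N)/N in [-1, 1]."""
        if self.N == 0:
            raise EmptyCoverageError("signal undefined for empty coverage")
        n_y = self.n_pos if y is Label.POSITIVE else self.n_neg
        L = 2
        return (L * n_y - self.N) / ((L - 1) * self.N)


class Hypothesis:
    """Abstract hypothesis implementing the three-clause contract."""

    kind = "ABSTRACT"

    def __init__(self, hyp_id: str, description: str = ""):
        self.id = hyp_id
        self.human_description = description or hyp_id
        self._stats_cache: tuple[str, HypothesisStats] | None = None

    # -- contract ----------------------------------------------------------
    def matches(self, mol: Molecule) -> bool:
        raise NotImplementedError

    def in_domain(self, mol: Molecule) -> bool:
        raise NotImplementedError

    def similarity(self, s1: Molecule, s2: Molecule) -> float:
        raise NotImplementedError

    # -- derived quantities ------------------------------------------------
    def coverage(self, dataset: ReferenceDataset) -> HypothesisStats:
        """C(h, D) with class counts; cached per dataset digest."""
        digest = dataset.digest()
        if self._stats_cache is not None and self._stats_cache[0] == digest:
            return self._stats_cache[1]
        covered, n_pos, n_neg = [], 0, 0
        for example in dataset:
            if self.matches(example.molecule):
                covered.append(example.id)
                if example.label is Label.POSITIVE:
                    n_pos += 1
                else:
                    n_neg += 1
        stats = HypothesisStats(frozenset(covered), n_pos, n_neg)
        self._stats_cache = (digest, stats)
        return stats

    def signal(self, dataset: ReferenceDataset, y: Label = Label.POSITIVE) -> float:
        return self.coverage(dataset).signal(y)

    def to_json(self) -> dict:
        return {"id": self.id, "kind": self.kind,
                "description": self.human_description}

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.id}>"


def _fingerprint_tanimoto(s1: Molecule, s2: Molecule) -> float:
    return s1.tanimoto(s2)


class RootHypothesis(Hypothesis):
    """h0: matches every structure; coverage is the whole reference dataset.

    The root guarantees that every query has at least one applicable
    hypothesis; its kNN fall-back runs over the entire dataset, so it uses
    the same structural fingerprint similarity as structural hypotheses.
    """

    kind = "ROOT"

    def __init__(self, hyp_id: str = "h0"):
        super().__init__(hyp_id, "root (matches any structure)")

    def matches(self, mol: Molecule) -> bool:
        return True

    def in_domain(self, mol: Molecule) -> bool:
        return True

    def similarity(self, s1: Molecule, s2: Molecule) -> float:
        return _fingerprint_tanimoto(s1, s2)


class StructuralHypothesis(Hypothesis):
    """A conjunction of fragments that must all be present.

    Extending the conjunction can only shrink the scope, hence the coverage —
    this monotonicity is what lets decision-tree paths map onto parent/child
    hypotheses.  The applicability domain is the shared fragment-dictionary
    rule (full atom-and-bond coverage by non-rare fragments); a hypothesis
    without an attached dictionary treats every structure as in-domain.
    """

    kind = "STRUCTURAL"

    def __init__(self, hyp_id: str, fragments: Sequence[Fragment],
                 dictionary: FragmentDictionary | None = None,
                 description: str = ""):
        if not fragments:
            raise ValueError("structural hypothesis needs >= 1 fragment")
        frags = sorted(fragments, key=lambda f: f.canonical_key)
        super().__init__(
            hyp_id,
            description or " AND ".join(f.canonical_key for f in frags),
        )
        self.fragments: tuple[Fragment, ...] = tuple(frags)
        self.dictionary = dictionary

    @property
    def fragment_keys(self) -> tuple[str, ...]:
        return tuple(f.canonical_key for f in self.fragments)

    def matches(self, mol: Molecule) -> bool:
        return all(f.matches(mol) for f in self.fragments)

    def in_domain(self, mol: Molecule) -> bool:
        if self.dictionary is None:
            return True
        return in_structural_domain(mol, self.dictionary).in_domain

    def similarity(self, s1: Molecule, s2: Molecule) -> float:
        return _fingerprint_tanimoto(s1, s2)

    def coverage(self, dataset: ReferenceDataset) -> HypothesisStats:
        # fast path: intersect the dictionary's presence sets when every
        # fragment is catalogued there (match-consistent by construction)
        if self.dictionary is not None and all(
            f.canonical_key in self.dictionary.presence for f in self.fragments
        ):
            digest = dataset.digest()
            if self._stats_cache is not None and self._stats_cache[0] == digest:
                return self._stats_cache[1]
            ids = frozenset(dataset.ids)
            for f in self.fragments:
                ids &= self.dictionary.presence[f.canonical_key]
            n_pos = sum(1 for i in ids if dataset[i].label is Label.POSITIVE)
            stats = HypothesisStats(ids, n_pos, len(ids) - n_pos)
            self._stats_cache = (digest, stats)
            return stats
        return super().coverage(dataset)

    def to_json(self) -> dict:
        return {**super().to_json(),
                "fragments": [f.to_json() for f in self.fragments]}


#: computable properties available to property-range hypotheses
PROPERTY_REGISTRY: dict[str, Callable] = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "tpsa": Descriptors.TPSA,
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
}


class PropertyRangeHypothesis(Hypothesis):
    """Scope: a computed property falls in a closed interval.

    Similarity is a normalised distance kernel exp(-|p1 - p2| / scale) with
    the scale defaulting to half the interval width (so two structures one
    full interval apart score ~0.14).
    """

    kind = "PROPERTY_RANGE"

    def __init__(self, hyp_id: str, property_name: str, low: float, high: float,
                 scale: float | None = None, description: str = ""):
        if low > high:
            raise ValueError("interval low must be <= high")
        if property_name not in PROPERTY_REGISTRY:
            raise ValueError(f"unknown property {property_name!r}")
        super().__init__(
            hyp_id, description or f"{property_name} in [{low}, {high}]"
        )
        self.property_name = property_name
        self.low = float(low)
        self.high = float(high)
        self.scale = scale if scale is not None else max((high - low) / 2.0, 1e-9)

    def _value(self, mol: Molecule) -> float | None:
        try:
            return float(PROPERTY_REGISTRY[self.property_name](mol.rdmol))
        except Exception:
            return None

    def matches(self, mol: Molecule) -> bool:
        value = self._value(mol)
        return value is not None and self.low <= value <= self.high

    def in_domain(self, mol: Molecule) -> bool:
        # a structure for which the property cannot be computed is outside
        # the domain rather than a non-match
        return self._value(mol) is not None

    def similarity(self, s1: Molecule, s2: Molecule) -> float:
        v1, v2 = self._value(s1), self._value(s2)
        if v1 is None or v2 is None:
            return 0.0
        return math.exp(-abs(v1 - v2) / self.scale)

    def to_json(self) -> dict:
        return {**super().to_json(), "property": self.property_name,
                "interval": [self.low, self.high], "scale": self.scale}


class ExampleHypothesis(Hypothesis):
    """A single observed data point as a maximally specific hypothesis.

    Its scope is the structures canonically identical to the example, so its
    signal magnitude is 1 (provided duplicates carry consistent labels).
    """

    kind = "EXAMPLE"

    def __init__(self, example: LabeledExample, hyp_id: str | None = None):
        super().__init__(hyp_id or f"ex:{example.id}",
                         f"example {example.id} ({example.label.value})")
        self.example = example

    def matches(self, mol: Molecule) -> bool:
        return mol.canonical_form == self.example.molecule.canonical_form

    def in_domain(self, mol: Molecule) -> bool:
        return True

    def similarity(self, s1: Molecule, s2: Molecule) -> float:
        return _fingerprint_tanimoto(s1, s2)

    def to_json(self) -> dict:
        return {**super().to_json(), "example_id": self.example.id,
                "smiles": self.example.molecule.canonical_form,
                "label": self.example.label.value}
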