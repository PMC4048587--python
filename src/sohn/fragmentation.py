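"""Reduced-feature-graph fragmentation and the fragment dictionary.

A molecule is first abstracted into a *reduced graph* whose nodes are
structural units — fused ring systems, functional groups matched greedily
from an ordered SMARTS table, and single leftover atoms — partitioning the
heavy atoms.  Fragments are then enumerated on the reduced graph as linear
unit paths plus circular unit neighbourhoods and expanded back to molecular
fragment graphs carrying attachment-point markers.  Enumerating on units
rather than raw atoms keeps chemically logical groups (rings, nitro groups,
...) intact inside every fragment.

The dictionary of fragments built over a reference dataset also defines the
structural applicability domain: a query is in-domain when every heavy atom
and every bond lies inside at least one match of a "non-rare" fragment (one
supported by at least ``min_support`` reference examples).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .chemio import Molecule, ReferenceDataset


class UnitKind(enum.Enum):
    RING_SYSTEM = "RING_SYSTEM"
    FUNCTIONAL_GROUP = "FUNCTIONAL_GROUP"
    ATOM = "ATOM"


@dataclass(frozen=True)
class StructuralUnit:
    kind: UnitKind
    atom_indices: frozenset[int]
    name: str = ""


@dataclass
class ReducedGraph:
    """Unit-level abstraction of a molecule; units partition the heavy atoms."""

    molecule: Molecule
    units: list[StructuralUnit]
    edges: list[tuple[int, int]]  # pairs of unit indices sharing a bond

    def neighbours(self, idx: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == idx:
                out.append(b)
            elif b == idx:
                out.append(a)
        return out


#: ordered functional-group table (greedy matching on non-ring atoms).
#: Halogens stay atomic units; 3-membered heterocycles are ring systems.
DEFAULT_UNIT_TABLE: tuple[tuple[str, str], ...] = (
    ("nitro", "[N+](=O)[O-]"),
    ("nitroso", "[NX2]=O"),
    ("sulfonic-acid", "S(=O)(=O)[OX2H1,OX1-]"),
    ("sulfonyl", "S(=O)(=O)"),
    ("carboxylic-acid", "C(=O)[OX2H1,OX1-]"),
    ("cyano", "C#N"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("amine", "[NX3;!$([NX3]=O)]"),
    ("hydroxyl", "[OX2H1]"),
    ("ether-oxygen", "[OX2H0]"),
)


def build_reduced_graph(
    mol: Molecule,
    unit_table: Sequence[tuple[str, str]] = DEFAULT_UNIT_TABLE,
) -> ReducedGraph:
    """Collapse a molecule into structural units.

    Fused rings (sharing at least one atom) merge into a single RING_SYSTEM
    unit; functional groups are matched greedily in table order on the
    remaining non-ring atoms; whatever is left becomes single-ATOM units.
    """
    rdmol = mol.rdmol
    n = rdmol.GetNumAtoms()
    claimed = [False] * n
    units: list[StructuralUnit] = []

    # 1. fused ring systems (union-find over rings sharing atoms)
    rings = [set(r) for r in rdmol.GetRingInfo().AtomRings()]
    merged = True
    while merged:
        merged = False
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if rings[i] & rings[j]:
                    rings[i] |= rings.pop(j)
                    merged = True
                    break
            if merged:
                break
    for ring in sorted(rings, key=min):
        units.append(StructuralUnit(UnitKind.RING_SYSTEM, frozenset(ring), "ring"))
        for idx in ring:
            claimed[idx] = True

    # 2. functional groups on unclaimed (non-ring) atoms, greedy in table order
    for name, smarts in unit_table:
        query = Chem.MolFromSmarts(smarts)
        for match in rdmol.GetSubstructMatches(query):
            if any(claimed[idx] for idx in match):
                continue
            units.append(StructuralUnit(UnitKind.FUNCTIONAL_GROUP, frozenset(match), name))
            for idx in match:
                claimed[idx] = True

    # 3. leftover atoms
    for idx in range(n):
        if not claimed[idx]:
            units.append(StructuralUnit(UnitKind.ATOM, frozenset([idx])))

    atom_to_unit = {}
    for u_idx, unit in enumerate(units):
        for a_idx in unit.atom_indices:
            atom_to_unit[a_idx] = u_idx
    edge_set = set()
    for bond in rdmol.GetBonds():
        ua = atom_to_unit[bond.GetBeginAtomIdx()]
        ub = atom_to_unit[bond.GetEndAtomIdx()]
        if ua != ub:
            edge_set.add((min(ua, ub), max(ua, ub)))
    return ReducedGraph(mol, units, sorted(edge_set))


def enumerate_fragments(
    rg: ReducedGraph, max_path_len: int = 3, circular_radius: int = 1
) -> list[frozenset[int]]:
    """Enumerate connected unit subgraphs: all simple paths of 1 to
    ``max_path_len`` units, plus each unit's neighbourhood of radius up to
    ``circular_radius``.  Returned as de-duplicated unit-index sets in a
    deterministic order."""
    if max_path_len < 1:
        raise ValueError("max_path_len must be >= 1")
    n = len(rg.units)
    adj = {i: sorted(rg.neighbours(i)) for i in range(n)}
    found: set[frozenset[int]] = set()

    def extend(path: list[int]) -> None:
        found.add(frozenset(path))
        if len(path) >= max_path_len:
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for start in range(n):
        extend([start])

    for start in range(n):
        ball = {start}
        frontier = {start}
        for _ in range(circular_radius):
            frontier = {v for u in frontier for v in adj[u]} - ball
            if not frontier:
                break
            ball |= frontier
        found.add(frozenset(ball))

    return sorted(found, key=lambda s: (len(s), sorted(s)))


@dataclass
class Fragment:
    """A connected molecular fragment with attachment-point markers.

    ``pattern`` is the display form (attachment points as ``*``);
    ``core_smiles`` drops the markers and is what substructure matching
    uses.  ``canonical_key`` is identical for identical patterns regardless
    of which molecule/unit selection produced them.
    """

    canonical_key: str
    core_smiles: str
    n_attachments: int
    support: int = 0
    _query: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def query(self) -> Chem.Mol:
        if self._query is None:
            q = Chem.MolFromSmiles(self.core_smiles)
            if q is None:
                q = Chem.MolFromSmarts(self.core_smiles)
            if q is None:
                raise ValueError(f"unmatchable fragment {self.core_smiles!r}")
            for atom in q.GetAtoms():
                # open valences left by severed bonds are attachment points,
                # not radicals; radical counts would veto substructure matches
                atom.SetNumRadicalElectrons(0)
            self._query = q
        return self._query

    def matches(self, mol: Molecule) -> bool:
        return mol.rdmol.HasSubstructMatch(self.query)

    def to_json(self) -> dict:
        return {
            "canonical_key": self.canonical_key,
            "core_smiles": self.core_smiles,
            "n_attachments": self.n_attachments,
            "support": self.support,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Fragment":
        return cls(
            canonical_key=obj["canonical_key"],
            core_smiles=obj["core_smiles"],
            n_attachments=obj["n_attachments"],
            support=obj.get("support", 0),
        )


def expand_fragment(rg: ReducedGraph, unit_subset: Iterable[int]) -> Fragment:
    """Expand a connected unit subgraph back to a molecular fragment.

    Severed bonds to the rest of the molecule become attachment points
    (dummy atoms in the display pattern, markers only — matching ignores
    them)."""
    rdmol = rg.molecule.rdmol
    atoms = set()
    for u_idx in unit_subset:
        atoms |= rg.units[u_idx].atom_indices

    core = Chem.MolFragmentToSmiles(rdmol, atomsToUse=sorted(atoms), canonical=True)

    # display form: mark boundary neighbours as dummy atoms, drop the rest
    rw = Chem.RWMol(rdmol)
    boundary = set()
    for bond in rdmol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in atoms) != (b in atoms):
            boundary.add(b if a in atoms else a)
    n_attach = len(boundary)
    for idx in boundary:
        atom = rw.GetAtomWithIdx(idx)
        atom.SetAtomicNum(0)
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(False)
    for bond in list(rw.GetBonds()):
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in boundary and b in boundary:
            rw.RemoveBond(a, b)
        elif a in boundary or b in boundary:
            rw.GetBondBetweenAtoms(a, b).SetBondType(Chem.BondType.SINGLE)
    for idx in sorted(set(range(rdmol.GetNumAtoms())) - atoms - boundary, reverse=True):
        rw.RemoveAtom(idx)
    display_mol = rw.GetMol()
    try:
        pattern = Chem.MolToSmiles(display_mol)
    except Exception:  # pragma: no cover - display only, never matching
        pattern = core
    return Fragment(canonical_key=pattern, core_smiles=core, n_attachments=n_attach)


@dataclass
class FragmentDictionary:
    """Fragments of a reference dataset with per-example presence sets.

    ``presence`` maps each canonical key to the frozen set of example ids
    containing the fragment (at least one substructure match); ``support``
    is the size of that set, counting examples, not occurrences.
    """

    fragments: dict[str, Fragment]
    presence: dict[str, frozenset[str]]
    min_support: int = 4

    def support(self, key: str) -> int:
        return len(self.presence.get(key, ()))

    def non_rare(self, key: str) -> bool:
        return self.support(key) >= self.min_support

    def non_rare_keys(self) -> list[str]:
        return sorted(k for k in self.fragments if self.non_rare(k))

    def __len__(self) -> int:
        return len(self.fragments)

    def to_json(self) -> dict:
        return {
            "min_support": self.min_support,
            "entries": [
                {
                    **self.fragments[k].to_json(),
                    "presence": sorted(self.presence[k]),
                }
                for k in sorted(self.fragments)
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FragmentDictionary":
        fragments, presence = {}, {}
        for entry in obj["entries"]:
            frag = Fragment.from_json(entry)
            frag.support = len(entry["presence"])
            fragments[frag.canonical_key] = frag
            presence[frag.canonical_key] = frozenset(entry["presence"])
        return cls(fragments, presence, obj["min_support"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FragmentDictionary":
        return cls.from_json(json.loads(Path(path).read_text()))


def build_fragment_dictionary(
    dataset: ReferenceDataset,
    max_path_len: int = 3,
    circular_radius: int = 1,
    min_support: int = 4,
    unit_table: Sequence[tuple[str, str]] = DEFAULT_UNIT_TABLE,
) -> FragmentDictionary:
    """Fragment every reference example and assemble the dictionary.

    Presence is decided by substructure matching (a fragment enumerated from
    one molecule may occur in another without being enumerated there), so
    support counts are match-consistent with hypothesis coverage."""
    fragments: dict[str, Fragment] = {}
    enumerated: dict[str, set[str]] = {}
    for example in dataset:
        rg = build_reduced_graph(example.molecule, unit_table)
        for subset in enumerate_fragments(rg, max_path_len, circular_radius):
            frag = expand_fragment(rg, subset)
            key = frag.canonical_key
            if key not in fragments:
                fragments[key] = frag
                enumerated[key] = set()
            enumerated[key].add(example.id)
    presence: dict[str, frozenset[str]] = {}
    for key, frag in fragments.items():
        present = set(enumerated[key])
        for example in dataset:
            if example.id not in present and frag.matches(example.molecule):
                present.add(example.id)
        presence[key] = frozenset(present)
        frag.support = len(present)
    return FragmentDictionary(fragments, presence, min_support)


@dataclass
class DomainReport:
    in_domain: bool
    uncovered_atoms: list[int]
    uncovered_bonds: list[tuple[int, int]]


def in_structural_domain(
    mol: Molecule, dictionary: FragmentDictionary
) -> DomainReport:
    """Applicability-domain check for structural hypotheses.

    True iff every heavy atom and every bond of the query lies inside at
    least one substructure match of at least one non-rare fragment."""
    rdmol = mol.rdmol
    atom_ok = [False] * rdmol.GetNumAtoms()
    bond_ok = [False] * rdmol.GetNumBonds()
    remaining_atoms = rdmol.GetNumAtoms()
    remaining_bonds = rdmol.GetNumBonds()
    for key in dictionary.non_rare_keys():
        frag = dictionary.fragments[key]
        query = frag.query
        matches = rdmol.GetSubstructMatches(query, maxMatches=200)
        for match in matches:
            for q_idx, m_idx in enumerate(match):
                if not atom_ok[m_idx]:
                    atom_ok[m_idx] = True
                    remaining_atoms -= 1
            for q_bond in query.GetBonds():
                m_bond = rdmol.GetBondBetweenAtoms(
                    match[q_bond.GetBeginAtomIdx()], match[q_bond.GetEndAtomIdx()]
                )
                if m_bond is not None and not bond_ok[m_bond.GetIdx()]:
                    bond_ok[m_bond.GetIdx()] = True
                    remaining_bonds -= 1
        if remaining_atoms == 0 and remaining_bonds == 0:
            return DomainReport(True, [], [])
    uncovered_atoms = [i for i, ok in enumerate(atom_ok) if not ok]
    uncovered_bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in rdmol.GetBonds()
        if not bond_ok[b.GetIdx()]
    ]
    return DomainReport(not (uncovered_atoms or uncovered_bonds),
                        uncovered_atoms, uncovered_bonds)
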