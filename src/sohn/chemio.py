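"""Molecule and dataset I/O plus a synthetic SAR dataset generator.

Structures are handled through RDKit.  Every molecule is sanitised once at
parse time (RDKit's default aromaticity model) and all downstream matching
operates on that sanitised graph, so substructure semantics are reproducible
across the whole pipeline.  Multi-component inputs (salts) are reduced to the
largest component by heavy-atom count.

The synthetic generator assembles molecules from a small scaffold/decoration
grammar and labels them with planted structure-activity rules (activating and
mitigating substructure patterns), giving a fully offline, seeded fixture in
which the "true" SAR is known.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs
from rdkit.Chem import rdmolops

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("sohn")


class ChemParseError(ValueError):
    """Raised when a structure or dataset cannot be parsed."""


class Label(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"

    @property
    def instance_signal(self) -> int:
        """+1 for a positive example, -1 for a negative one."""
        return 1 if self is Label.POSITIVE else -1


#: case-insensitive aliases accepted when reading label columns
LABEL_ALIASES = {
    "1": Label.POSITIVE,
    "0": Label.NEGATIVE,
    "pos": Label.POSITIVE,
    "neg": Label.NEGATIVE,
    "positive": Label.POSITIVE,
    "negative": Label.NEGATIVE,
    "active": Label.POSITIVE,
    "inactive": Label.NEGATIVE,
    "mutagen": Label.POSITIVE,
    "non-mutagen": Label.NEGATIVE,
    "nonmutagen": Label.NEGATIVE,
    "non mutagen": Label.NEGATIVE,
}


def parse_label(value) -> Label:
    key = str(value).strip().lower()
    if key in LABEL_ALIASES:
        return LABEL_ALIASES[key]
    raise ChemParseError(f"unknown class label {value!r}")


class Molecule:
    """A sanitised chemical structure with a stable canonical form.

    Parameters
    ----------
    rdmol:
        A sanitised RDKit molecule (single component).
    mol_id:
        Identifier; defaults to the canonical SMILES.
    """

    __slots__ = ("id", "rdmol", "canonical_form", "_fingerprint")

    def __init__(self, rdmol: Chem.Mol, mol_id: str | None = None):
        self.rdmol = rdmol
        self.canonical_form = Chem.MolToSmiles(rdmol)
        self.id = mol_id if mol_id is not None else self.canonical_form
        self._fingerprint = None

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def fingerprint(self):
        """Hashed linear-path fingerprint (paths up to 7 bonds, 2048 bits).

        Used by the structural similarity clause (Tanimoto index); computed
        lazily and cached on the molecule.
        """
        if self._fingerprint is None:
            self._fingerprint = Chem.RDKFingerprint(
                self.rdmol, maxPath=7, fpSize=2048
            )
        return self._fingerprint

    def tanimoto(self, other: "Molecule") -> float:
        # single-atom molecules have no paths, hence empty fingerprints;
        # fall back to identity comparison instead of the 0/0 convention
        if (self.fingerprint.GetNumOnBits() == 0
                or other.fingerprint.GetNumOnBits() == 0):
            return 1.0 if self.canonical_form == other.canonical_form else 0.0
        return DataStructs.TanimotoSimilarity(self.fingerprint, other.fingerprint)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule({self.id!r}, {self.canonical_form!r})"


def parse_molecule(text: str, mol_id: str | None = None) -> Molecule:
    """Parse a SMILES string (or MDL mol block) into a :class:`Molecule`.

    Multi-component structures are reduced to the largest component by
    heavy-atom count; the removal is logged.

    Raises
    ------
    ChemParseError
        If the text is empty or cannot be parsed/sanitised.
    """
    if not text or not text.strip():
        raise ChemParseError("empty structure input")
    text = text.strip()
    if "\n" in text or text.startswith("M  END"):
        rdmol = Chem.MolFromMolBlock(text)
    else:
        rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise ChemParseError(f"unparseable structure: {text.splitlines()[0]!r}")
    frags = rdmolops.GetMolFrags(rdmol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        rdmol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.info(
            "multi-component structure %s: kept largest component of %d",
            mol_id or text,
            len(frags),
        )
    return Molecule(rdmol, mol_id)


@dataclass(frozen=True)
class LabeledExample:
    """A molecule with a binary activity class."""

    molecule: Molecule
    label: Label

    @property
    def id(self) -> str:
        return self.molecule.id

    @property
    def instance_signal(self) -> int:
        return self.label.instance_signal


class ReferenceDataset:
    """An ordered collection of labelled examples over two classes.

    The reference dataset anchors every coverage computation: hypothesis
    generality is defined relative to it, and its examples are the supporting
    evidence used by the kNN local predictions.
    """

    def __init__(self, examples: Sequence[LabeledExample]):
        ids = [e.id for e in examples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate example ids: {dupes[:5]}")
        self.examples: list[LabeledExample] = list(examples)
        self._by_id = {e.id: e for e in self.examples}

    classes = (Label.POSITIVE, Label.NEGATIVE)

    @property
    def L(self) -> int:
        """Number of classes (binary here)."""
        return 2

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self):
        return iter(self.examples)

    def __getitem__(self, example_id: str) -> LabeledExample:
        return self._by_id[example_id]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.examples]

    def subset(self, ids: Iterable[str]) -> "ReferenceDataset":
        wanted = set(ids)
        return ReferenceDataset([e for e in self.examples if e.id in wanted])

    def class_counts(self) -> dict[Label, int]:
        counts = {Label.POSITIVE: 0, Label.NEGATIVE: 0}
        for e in self.examples:
            counts[e.label] += 1
        return counts

    def digest(self) -> str:
        # datasets are treated as immutable once built; cache the digest
        cached = getattr(self, "_digest", None)
        if cached is not None:
            return cached
        import hashlib

        h = hashlib.sha256()
        for e in self.examples:
            h.update(f"{e.id}\t{e.molecule.canonical_form}\t{e.label.value}\n".encode())
        self._digest = h.hexdigest()[:16]
        return self._digest

    def deduplicate(self, policy: str = "drop-conflicts") -> "ReferenceDataset":
        """Collapse duplicate structures.

        ``drop-conflicts`` (default) removes all copies of a structure whose
        duplicates disagree on the label and keeps the first copy of
        consistent duplicates; ``keep-first`` always keeps the first copy.
        """
        by_canon: dict[str, list[LabeledExample]] = {}
        for e in self.examples:
            by_canon.setdefault(e.molecule.canonical_form, []).append(e)
        kept = []
        for canon, group in by_canon.items():
            labels = {e.label for e in group}
            if len(labels) > 1 and policy == "drop-conflicts":
                logger.warning(
                    "dropping %d conflicting duplicates of %s", len(group), canon
                )
                continue
            kept.append(group[0])
        order = {e.id: i for i, e in enumerate(self.examples)}
        kept.sort(key=lambda e: order[e.id])
        return ReferenceDataset(kept)


# ---------------------------------------------------------------------------
# dataset readers / writers
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    fmt: str = "smiles-csv",
    label_field: str = "label",
    on_parse_error: str = "skip",
) -> ReferenceDataset:
    """Read a labelled dataset from delimited text or SDF.

    ``smiles-csv`` expects columns ``id``, ``smiles`` and the label column;
    ``sdf`` reads the activity from the named property field.  Parse failures
    are skipped with a warning (``on_parse_error='skip'``) or fatal
    (``'fatal'``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    examples: list[LabeledExample] = []
    bad_labels: list[str] = []
    if fmt == "smiles-csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ChemParseError("empty dataset")
            for row_idx, row in enumerate(reader):
                try:
                    mol = parse_molecule(row["smiles"], row.get("id") or f"row{row_idx}")
                except ChemParseError as exc:
                    if on_parse_error == "fatal":
                        raise ChemParseError(f"row {row_idx}: {exc}") from exc
                    logger.warning("skipping row %d: %s", row_idx, exc)
                    continue
                try:
                    label = parse_label(row[label_field])
                except ChemParseError:
                    bad_labels.append(f"row {row_idx}: {row[label_field]!r}")
                    continue
                examples.append(LabeledExample(mol, label))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for row_idx, rdmol in enumerate(supplier):
            if rdmol is None:
                if on_parse_error == "fatal":
                    raise ChemParseError(f"record {row_idx}: unparseable structure")
                logger.warning("skipping record %d: unparseable structure", row_idx)
                continue
            mol_id = (
                rdmol.GetProp("_Name")
                if rdmol.HasProp("_Name") and rdmol.GetProp("_Name")
                else f"rec{row_idx}"
            )
            if not rdmol.HasProp(label_field):
                bad_labels.append(f"record {row_idx}: missing {label_field}")
                continue
            try:
                label = parse_label(rdmol.GetProp(label_field))
            except ChemParseError:
                bad_labels.append(f"record {row_idx}: {rdmol.GetProp(label_field)!r}")
                continue
            examples.append(LabeledExample(Molecule(rdmol, mol_id), label))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if bad_labels:
        raise ChemParseError("unknown label values: " + "; ".join(bad_labels))
    if not examples:
        raise ChemParseError("empty dataset")
    return ReferenceDataset(examples)


def write_dataset(dataset: ReferenceDataset, path: str | Path, fmt: str = "smiles-csv",
                  label_field: str = "label") -> None:
    path = Path(path)
    if fmt == "smiles-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", label_field])
            for e in dataset:
                writer.writerow([e.id, e.molecule.canonical_form, e.label.value])
    elif fmt == "sdf":
        with Chem.SDWriter(str(path)) as writer:
            for e in dataset:
                rdmol = Chem.Mol(e.molecule.rdmol)
                rdmol.SetProp("_Name", e.id)
                rdmol.SetProp(label_field, e.label.value)
                writer.write(rdmol)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# synthetic dataset generator
# ---------------------------------------------------------------------------

class RuleEffect(enum.Enum):
    ACTIVATING = "ACTIVATING"
    MITIGATING = "MITIGATING"


@dataclass(frozen=True)
class SyntheticRule:
    """A planted substructure rule used to label generated molecules."""

    pattern: str  # SMARTS
    effect: RuleEffect
    fire_probability: float = 1.0
    name: str = ""

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.pattern)
        if q is None:
            raise ValueError(f"invalid rule pattern {self.pattern!r}")
        return q


#: planted rule set mirroring classic mutagenicity toxicophores: aromatic
#: nitro / aromatic primary amine / strained three-membered heterocycles
#: activate, a sulfonate meta to the nitro group mitigates.
DEFAULT_RULES: tuple[SyntheticRule, ...] = (
    SyntheticRule("c[N+](=O)[O-]", RuleEffect.ACTIVATING, name="aromatic-nitro"),
    SyntheticRule("c[NX3;H2]", RuleEffect.ACTIVATING, name="aromatic-amine"),
    SyntheticRule("C1CO1", RuleEffect.ACTIVATING, name="epoxide"),
    SyntheticRule("C1CN1", RuleEffect.ACTIVATING, name="aziridine"),
    SyntheticRule(
        "OS(=O)(=O)c1cccc([N+](=O)[O-])c1",
        RuleEffect.MITIGATING,
        name="meta-sulfonate",
    ),
)

# scaffold/decoration grammar ------------------------------------------------

_AROMATIC_SCAFFOLDS = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1ccc(-c2ccccc2)cc1", # biphenyl
]
_ALIPHATIC_SCAFFOLDS = [
    "C1CCCCC1",            # cyclohexane
    "C1CCc2ccccc2C1",      # tetralin (decorated on the saturated ring)
]

# decoration fragments: SMILES whose atom 0 is the attachment atom, with the
# sampling probability per molecule.  Nitro and amine are restricted to
# aromatic scaffolds (arene chemistry); the rest attach anywhere.
_DECORATIONS: dict[str, tuple[str, float, bool]] = {
    # name: (smiles, probability, aromatic_only)
    "nitro": ("[N+](=O)[O-]", 0.65, True),
    "amine": ("N", 0.30, True),
    "sulfo": ("S(=O)(=O)O", 0.10, False),
    "methyl": ("C", 0.30, False),
    "ethyl": ("CC", 0.10, False),
    "chloro": ("Cl", 0.20, False),
    "fluoro": ("F", 0.10, False),
    "bromo": ("Br", 0.05, False),
    "hydroxyl": ("O", 0.15, False),
    "methoxy": ("OC", 0.15, False),
    "carboxy": ("C(=O)O", 0.10, False),
    "acetyl": ("C(C)=O", 0.10, False),
    "cyano": ("C#N", 0.10, False),
    "nitroso": ("N=O", 0.05, False),
    "epoxide": ("C1CO1", 0.05, False),
    "aziridine": ("C1CN1", 0.05, False),
}

#: probability that a generated molecule is the deliberate "mitigated"
#: combination (benzene bearing a nitro group with a sulfonate in meta).
_MITIGATED_COMBO_P = 0.02


def _attachment_sites(rdmol: Chem.Mol, aromatic_only: bool) -> list[int]:
    sites = []
    for atom in rdmol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() < 1:
            continue
        if aromatic_only and not atom.GetIsAromatic():
            continue
        sites.append(atom.GetIdx())
    return sites


def _attach(rdmol: Chem.Mol, deco_smiles: str, site: int) -> Chem.Mol:
    deco = Chem.MolFromSmiles(deco_smiles)
    combined = Chem.RWMol(Chem.CombineMols(rdmol, deco))
    combined.AddBond(site, rdmol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def _build_molecule(rng: np.random.Generator) -> Chem.Mol:
    """Sample one molecule from the scaffold/decoration grammar."""
    if rng.random() < _MITIGATED_COMBO_P:
        # deliberate mitigated combination: nitro + meta sulfonate on benzene
        rdmol = Chem.MolFromSmiles("c1ccccc1")
        rdmol = _attach(rdmol, _DECORATIONS["nitro"][0], 0)
        rdmol = _attach(rdmol, _DECORATIONS["sulfo"][0], 2)
        return rdmol
    aromatic = rng.random() < 0.8
    pool = _AROMATIC_SCAFFOLDS if aromatic else _ALIPHATIC_SCAFFOLDS
    rdmol = Chem.MolFromSmiles(pool[rng.integers(len(pool))])
    chosen = []
    has_nitro = False
    for name, (smiles, prob, arom_only) in _DECORATIONS.items():
        if arom_only and not aromatic:
            continue
        if rng.random() >= prob:
            continue
        if name == "nitro":
            has_nitro = True
        if name == "sulfo" and has_nitro:
            # nitro/sulfonate co-occurrence is generated only through the
            # deliberate mitigated combination above
            continue
        chosen.append(smiles)
    for smiles in chosen:
        sites = _attachment_sites(rdmol, aromatic)
        if not sites:
            break
        site = int(sites[rng.integers(len(sites))])
        rdmol = _attach(rdmol, smiles, site)
    return rdmol


def label_molecule(rdmol: Chem.Mol, rules: Sequence[SyntheticRule],
                   rng: np.random.Generator | None = None) -> Label:
    """Planted-rule label: positive iff an activating rule fires and no
    applicable mitigating rule fires."""
    activated = mitigated = False
    for rule in rules:
        if not rdmol.HasSubstructMatch(rule.query()):
            continue
        if rule.fire_probability < 1.0:
            if rng is None or rng.random() >= rule.fire_probability:
                continue
        if rule.effect is RuleEffect.ACTIVATING:
            activated = True
        else:
            mitigated = True
    return Label.POSITIVE if activated and not mitigated else Label.NEGATIVE


def generate_synthetic_dataset(
    n: int,
    rules: Sequence[SyntheticRule] = DEFAULT_RULES,
    seed: int = 0,
    noise: float = 0.0,
) -> ReferenceDataset:
    """Generate ``n`` labelled molecules with planted SAR rules.

    Labels are a pure function of the molecule and the rules, then flipped
    independently with probability ``noise``.  Identical seeds give
    byte-identical datasets.  Duplicate generated structures are kept as
    distinct examples (distinct ids), mirroring real datasets with repeated
    measurements.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not rules:
        raise ValueError("rules must be non-empty")
    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n):
        rdmol = _build_molecule(rng)
        label = label_molecule(rdmol, rules, rng)
        if noise > 0 and rng.random() < noise:
            label = Label.NEGATIVE if label is Label.POSITIVE else Label.POSITIVE
        examples.append(LabeledExample(Molecule(rdmol, f"syn{i:04d}"), label))
    return ReferenceDataset(examples)
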