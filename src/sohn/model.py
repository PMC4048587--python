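"""Model persistence: one JSON bundle for the whole predictive artifact.

The reference dataset becomes part of the network (its examples are the
supporting evidence of every kNN prediction), so the bundle contains the
dataset itself alongside the fragment dictionary, the mined hypotheses, the
optional calibration model and the configuration digest.  The network edges
are not stored: the Hasse diagram is uniquely determined by the coverages,
so it is rebuilt deterministically on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .chemio import LabeledExample, Molecule, ReferenceDataset, parse_label, parse_molecule
from .config import RunConfig
from .evaluate import CalibrationModel
from .fragmentation import FragmentDictionary, build_fragment_dictionary
from .hypotheses import StructuralHypothesis
from .mining import mine_hypotheses
from .network import SOHNNetwork, build_sohn


@dataclass
class SOHNModel:
    """A trained SOHN bundle ready for prediction."""

    reference: ReferenceDataset
    dictionary: FragmentDictionary
    hypotheses: list[StructuralHypothesis]
    network: SOHNNetwork
    calibration: CalibrationModel | None
    config_digest: str

    @classmethod
    def train(cls, dataset: ReferenceDataset, config: RunConfig | None = None,
              calibration: CalibrationModel | None = None) -> "SOHNModel":
        config = config or RunConfig()
        config.validate()
        dictionary = build_fragment_dictionary(
            dataset,
            max_path_len=config.max_path_len,
            circular_radius=config.circular_radius,
            min_support=config.min_support,
        )
        hypotheses = mine_hypotheses(dataset, dictionary, config.mining_config())
        network = build_sohn(hypotheses, dataset, dictionary)
        return cls(dataset, dictionary, hypotheses, network, calibration,
                   config.digest())

    def to_json(self) -> dict:
        return {
            "format": "sohn-model",
            "version": 1,
            "config_digest": self.config_digest,
            "reference_digest": self.reference.digest(),
            "dataset": [
                {"id": e.id, "smiles": e.molecule.canonical_form,
                 "label": e.label.value}
                for e in self.reference
            ],
            "dictionary": self.dictionary.to_json(),
            "hypotheses": [
                {"id": h.id, "fragment_keys": list(h.fragment_keys)}
                for h in self.hypotheses
            ],
            "calibration": None if self.calibration is None
            else self.calibration.to_json(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, obj: dict) -> "SOHNModel":
        if obj.get("format") != "sohn-model":
            raise ValueError("not a SOHN model file")
        examples = [
            LabeledExample(parse_molecule(row["smiles"], row["id"]),
                           parse_label(row["label"]))
            for row in obj["dataset"]
        ]
        reference = ReferenceDataset(examples)
        if reference.digest() != obj["reference_digest"]:
            raise ValueError("reference dataset digest mismatch")
        dictionary = FragmentDictionary.from_json(obj["dictionary"])
        hypotheses = [
            StructuralHypothesis(
                row["id"],
                [dictionary.fragments[k] for k in row["fragment_keys"]],
                dictionary=dictionary,
            )
            for row in obj["hypotheses"]
        ]
        network = build_sohn(hypotheses, reference, dictionary)
        calibration = (
            CalibrationModel.from_json(obj["calibration"])
            if obj.get("calibration") else None
        )
        return cls(reference, dictionary, hypotheses, network, calibration,
                   obj["config_digest"])

    @classmethod
    def load(cls, path: str | Path) -> "SOHNModel":
        return cls.from_json(json.loads(Path(path).read_text()))
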