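"""Run configuration: documented defaults, plain-text config files, digests.

Every tunable of the pipeline lives here with its default: fragmentation
depth (``max_path_len`` 3, ``circular_radius`` 1), the non-rare fragment
support threshold (``min_support`` 4), tree growth controls, the kNN size
``k`` = 10, the decision-band parameters ``a`` = 0 and ``b`` = 0, and the
evaluation settings (5 folds, 5 calibration bins).  Configs serialise to a
``key = value`` text file; a short digest of the effective configuration is
embedded in every artifact so mismatched models and dictionaries can be
refused.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .evaluate import CVConfig
from .mining import MiningConfig
from .predict import PredictConfig


@dataclass
class RunConfig:
    # fragmentation
    max_path_len: int = 3
    circular_radius: int = 1
    min_support: int = 4
    # mining
    min_node_size: int = 4
    max_depth: int = 8
    min_gain: float = 0.0
    min_coverage: int = 4
    min_abs_signal: float = 0.0
    emit_mode: str = "path"
    # prediction
    k: int = 10
    a: float = 0.0
    b: float = 0.0
    similarity_exponent: float = 0.5
    divide_by_k_used: bool = False
    ignore_overruled: bool = False
    # evaluation
    folds: int = 5
    bins: int = 5
    seed: int = 0
    # io
    label_field: str = "label"
    dataset_format: str = "smiles-csv"
    dedup_policy: str = "drop-conflicts"
    # synthetic data
    n_molecules: int = 500
    noise: float = 0.05

    _RANGES = {
        "max_path_len": (1, 10),
        "circular_radius": (0, 5),
        "min_support": (1, 10**6),
        "min_node_size": (1, 10**6),
        "max_depth": (1, 64),
        "min_coverage": (1, 10**6),
        "k": (1, 10**4),
        "folds": (2, 100),
        "bins": (2, 100),
        "similarity_exponent": (0.0, 4.0),
        "noise": (0.0, 1.0),
        "b": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"config {name}={value!r} outside [{lo}, {hi}]")
        if self.emit_mode not in ("path", "node"):
            raise ValueError(f"emit_mode must be 'path' or 'node'")

    # -- sub-configs -------------------------------------------------------
    def mining_config(self) -> MiningConfig:
        return MiningConfig(
            min_node_size=self.min_node_size,
            max_depth=self.max_depth,
            min_gain=self.min_gain,
            min_coverage=self.min_coverage,
            min_abs_signal=self.min_abs_signal,
            emit_mode=self.emit_mode,
        )

    def predict_config(self, attach_paths: bool = True) -> PredictConfig:
        return PredictConfig(
            k=self.k, a=self.a, b=self.b,
            similarity_exponent=self.similarity_exponent,
            divide_by_k_used=self.divide_by_k_used,
            ignore_overruled=self.ignore_overruled,
            attach_paths=attach_paths,
        )

    def cv_config(self) -> CVConfig:
        return CVConfig(
            folds=self.folds, seed=self.seed,
            max_path_len=self.max_path_len,
            circular_radius=self.circular_radius,
            min_support=self.min_support,
            mining=self.mining_config(),
            prediction=self.predict_config(attach_paths=False),
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def digest(self) -> str:
        payload = "\n".join(f"{k}={v}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        config = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if not hasattr(config, key) or key.startswith("_"):
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(config, key)
            if isinstance(current, bool):
                value: object = raw.lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(config, key, value)
        config.validate()
        return config
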