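"""Cross-validation, confusion metrics and confidence standardisation.

The raw confidence |s_x| correlates with accuracy monotonically but not
linearly.  To obtain a *standard confidence* that tracks expected accuracy,
cross-validated predictions are pooled into equidistant raw-confidence bins,
an order-3 polynomial is fitted from raw confidence to observed bin accuracy
(weighted by bin occupancy), and the fit is anchored by the affine map
accuracy -> 2*accuracy - 1, so that coin-flip accuracy (0.5) maps to
standard confidence 0 and perfect accuracy to 1.  The transformation is
clipped to [0, 1] and forced non-decreasing by isotonic projection of the
fitted curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .chemio import Label, ReferenceDataset
from .fragmentation import build_fragment_dictionary
from .mining import MiningConfig, mine_hypotheses
from .network import build_sohn
from .predict import PredictConfig, predict

logger = logging.getLogger("sohn")


@dataclass(frozen=True)
class PredictionRecord:
    example_id: str
    true_class: Label
    predicted_class: Label | None  # None = equivocal
    raw_confidence: float
    standard_confidence: float | None
    hypothesis_count: int

    @property
    def is_equivocal(self) -> bool:
        return self.predicted_class is None

    @property
    def is_correct(self) -> bool:
        return self.predicted_class is self.true_class


@dataclass
class PerformanceMetrics:
    """Binary confusion metrics; undefined ratios are None, never 0."""

    TP: int
    FP: int
    TN: int
    FN: int
    equivocal: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def SEN(self) -> float | None:
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def SPEC(self) -> float | None:
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def BAC(self) -> float | None:
        if self.SEN is None or self.SPEC is None:
            return None
        return (self.SEN + self.SPEC) / 2

    @property
    def PPV(self) -> float | None:
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def NPV(self) -> float | None:
        return self._ratio(self.TN, self.TN + self.FN)

    def to_json(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "equivocal": self.equivocal,
            "BAC": self.BAC, "SEN": self.SEN, "SPEC": self.SPEC,
            "PPV": self.PPV, "NPV": self.NPV,
        }


def compute_metrics(
    records: list[PredictionRecord], equivocal_policy: str = "exclude"
) -> PerformanceMetrics:
    """Confusion metrics with explicit equivocal handling.

    ``exclude`` drops equivocal predictions from the confusion matrix (they
    are still counted separately); ``count-as-error`` scores an equivocal
    call as a miss for the true class.
    """
    if equivocal_policy not in ("exclude", "count-as-error"):
        raise ValueError(f"unknown equivocal policy {equivocal_policy!r}")
    tp = fp = tn = fn = eq = 0
    for r in records:
        if r.is_equivocal:
            eq += 1
            if equivocal_policy == "count-as-error":
                if r.true_class is Label.POSITIVE:
                    fn += 1
                else:
                    fp += 1
            continue
        if r.true_class is Label.POSITIVE:
            if r.predicted_class is Label.POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if r.predicted_class is Label.NEGATIVE:
                tn += 1
            else:
                fp += 1
    if equivocal_policy == "exclude" and tp + fp + tn + fn == 0:
        raise ValueError("no non-equivocal records to score")
    return PerformanceMetrics(tp, fp, tn, fn, eq)


@dataclass
class CalibrationModel:
    """Order-3 polynomial standardisation of the raw confidence.

    ``coefficients`` are the polynomial mapping raw confidence to predicted
    accuracy (numpy ``polyval`` order); the standard confidence is
    clip(2*accuracy - 1, 0, 1), tabulated on a grid with isotonic projection
    so the final transform is non-decreasing.
    """

    coefficients: list[float]
    bin_table: list[dict]  # bin centre, mean raw, accuracy, count
    grid: np.ndarray = field(repr=False, default=None)
    values: np.ndarray = field(repr=False, default=None)
    identity: bool = False

    def __post_init__(self):
        if self.grid is None:
            self._tabulate()

    def _tabulate(self) -> None:
        self.grid = np.linspace(0.0, 1.0, 201)
        if self.identity:
            self.values = self.grid.copy()
            return
        accuracy = np.polyval(self.coefficients, self.grid)
        standard = np.clip(2.0 * accuracy - 1.0, 0.0, 1.0)
        self.values = np.maximum.accumulate(standard)  # isotonic projection

    def transform(self, raw_confidence) -> np.ndarray | float:
        raw = np.clip(np.asarray(raw_confidence, dtype=float), 0.0, 1.0)
        out = np.interp(raw, self.grid, self.values)
        return float(out) if np.isscalar(raw_confidence) else out

    def to_json(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "bin_table": self.bin_table,
            "identity": self.identity,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CalibrationModel":
        return cls(obj["coefficients"], obj["bin_table"], identity=obj["identity"])

    @classmethod
    def identity_model(cls) -> "CalibrationModel":
        return cls([], [], identity=True)


def fit_calibration(
    records: list[PredictionRecord], bins: int = 5
) -> CalibrationModel:
    """Fit the standard-confidence transform from cross-validation records.

    Raw confidences are pooled into ``bins`` equidistant bins on [0, 1];
    per-bin observed accuracy (over non-equivocal predictions) is fitted by
    a weighted least-squares polynomial of order min(3, non-empty bins - 1).
    Fewer than 3 non-empty bins fall back to the identity transform.
    """
    scored = [r for r in records if not r.is_equivocal]
    edges = np.linspace(0.0, 1.0, bins + 1)
    raw = np.array([r.raw_confidence for r in scored])
    correct = np.array([r.is_correct for r in scored], dtype=float)
    idx = np.clip(np.digitize(raw, edges) - 1, 0, bins - 1)
    table = []
    for b in range(bins):
        mask = idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        table.append({
            "bin_centre": float((edges[b] + edges[b + 1]) / 2),
            "mean_raw": float(raw[mask].mean()),
            "accuracy": float(correct[mask].mean()),
            "count": count,
        })
    if len(table) < 3:
        logger.warning(
            "calibration: only %d non-empty bins, using identity transform",
            len(table),
        )
        return CalibrationModel.identity_model()
    degree = min(3, len(table) - 1)
    x = np.array([row["mean_raw"] for row in table])
    yy = np.array([row["accuracy"] for row in table])
    w = np.sqrt([row["count"] for row in table])  # polyfit weights scale residuals
    coeffs = np.polyfit(x, yy, deg=degree, w=w)
    return CalibrationModel(list(coeffs), table)


def apply_calibration(
    records: list[PredictionRecord], model: CalibrationModel
) -> list[PredictionRecord]:
    return [
        PredictionRecord(
            r.example_id, r.true_class, r.predicted_class, r.raw_confidence,
            float(model.transform(r.raw_confidence)), r.hypothesis_count,
        )
        for r in records
    ]


@dataclass
class CVConfig:
    folds: int = 5
    seed: int = 0
    max_path_len: int = 3
    circular_radius: int = 1
    min_support: int = 4
    mining: MiningConfig = field(default_factory=MiningConfig)
    prediction: PredictConfig = field(
        default_factory=lambda: PredictConfig(attach_paths=False)
    )


@dataclass
class FoldDetail:
    """Per-fold training artifacts, exposed for leakage auditing."""

    fold: int
    train_ids: list[str]
    test_ids: list[str]
    dictionary: object
    hypotheses: list


def cross_validate(
    dataset: ReferenceDataset,
    config: CVConfig | None = None,
    fold_details: list | None = None,
) -> list[PredictionRecord]:
    """Stratified k-fold cross-validation of the full pipeline.

    For every fold the fragment dictionary, the mined hypotheses and the
    network are built from the training folds only, so held-out examples
    never influence the descriptors or the tree.  Pass a list as
    ``fold_details`` to receive one :class:`FoldDetail` per fold.
    """
    config = config or CVConfig()
    if len(dataset) < config.folds:
        raise ValueError("dataset smaller than the number of folds")
    y = [e.label.value for e in dataset]
    ids = np.array(dataset.ids)
    splitter = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    records: list[PredictionRecord] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(ids, y)):
        train = dataset.subset(ids[train_idx])
        counts = train.class_counts()
        if min(counts.values()) == 0:
            raise ValueError(
                f"fold {fold}: a class is absent from the training folds; "
                "provide more data or fewer folds"
            )
        dictionary = build_fragment_dictionary(
            train,
            max_path_len=config.max_path_len,
            circular_radius=config.circular_radius,
            min_support=config.min_support,
        )
        hypotheses = mine_hypotheses(train, dictionary, config.mining)
        net = build_sohn(hypotheses, train, dictionary)
        for i in test_idx:
            example = dataset.examples[int(i)]
            result = predict(net, example.molecule, config=config.prediction)
            records.append(
                PredictionRecord(
                    example.id,
                    example.label,
                    result.predicted_class,
                    result.raw_confidence,
                    None,
                    result.m,
                )
            )
        logger.info("fold %d: %d hypotheses, %d test predictions",
                    fold, len(hypotheses), len(test_idx))
        if fold_details is not None:
            fold_details.append(FoldDetail(
                fold, list(ids[train_idx]), list(ids[test_idx]),
                dictionary, hypotheses,
            ))
    return records


def hypothesis_count_distribution(records: list[PredictionRecord]) -> dict:
    """Histogram of the number of hypotheses per prediction, with the
    fraction of predictions using at most 4 hypotheses."""
    counts: dict[int, int] = {}
    for r in records:
        counts[r.hypothesis_count] = counts.get(r.hypothesis_count, 0) + 1
    total = sum(counts.values())
    return {
        "histogram": dict(sorted(counts.items())),
        "fractions": {m: c / total for m, c in sorted(counts.items())},
        "fraction_le_4": sum(c for m, c in counts.items() if m <= 4) / total,
    }
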