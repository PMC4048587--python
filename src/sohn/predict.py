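"""Prediction from a SOHN: relevant hypotheses, local kNN calls, global call.

For a query x the network is searched for the *relevant hypotheses*: every
hypothesis that matches x, has x in its applicability domain, and has no
matching in-domain strict descendant.  The root matches everything, so the
set is never empty; an exact structural match makes the corresponding
example node the single relevant hypothesis.

Each relevant hypothesis then makes a local instance-based prediction from
its supporting examples: the k nearest neighbours by the hypothesis's own
similarity clause are weighted by the square root of their similarity,

    w_i = sqrt(Similarity(x, e_i))
    ws  = sum(w_i * s_i) / sum(w_i)          (similarity-weighted signal)
    S   = ws * sum(w_i) / k = sum(w_i * s_i) / k

where s_i is the instance signal (+1/-1).  Dividing by k rather than by the
number of neighbours found moderates the signal toward equivocal when the
support is thin or distant.  The sign of S gives the local class, |S| the
local confidence.  A local prediction whose sign contradicts the
hypothesis's own reference signal is flagged *overruled*.

The overall call weights each local signal by its confidence:

    s_x = sum(S_h * conf_h) / sum(conf_h)

and classifies with the decision band: positive if s_x > a + b, negative if
s_x < a - b, otherwise equivocal (a shifts the class threshold, b widens the
equivocal band to trade coverage for reliability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chemio import Label, Molecule, ReferenceDataset
from .hypotheses import Hypothesis
from .network import ROOT_ID, SARPath, SOHNNetwork


@dataclass(frozen=True)
class Neighbour:
    example_id: str
    similarity: float
    weight: float
    instance_signal: int


@dataclass
class LocalPrediction:
    hypothesis_id: str
    neighbours: list[Neighbour]
    k_used: int
    weighted_signal: float   # ws_h,x
    signal: float            # S_h,x in [-1, 1]
    predicted_class: Label | None  # None encodes an equivocal local call
    confidence: float
    overruled: bool


@dataclass
class GlobalPrediction:
    query_id: str
    relevant_hypotheses: list[str]
    locals: list[LocalPrediction]
    overall_signal: float
    a: float
    b: float
    predicted_class: Label | None
    raw_confidence: float
    standard_confidence: float | None = None
    sar_paths: dict[str, list[SARPath]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Number of relevant hypotheses used."""
        return len(self.relevant_hypotheses)


def find_relevant_hypotheses(net: SOHNNetwork, query: Molecule) -> list[str]:
    """Most specific matching, in-domain hypotheses for the query.

    Nodes that match but fail the domain clause are passed through (their
    in-domain descendants stay reachable); the result is de-duplicated
    regardless of how many DAG routes lead to a node, and falls back to the
    root when nothing else applies.
    """
    match_cache: dict[str, bool] = {}
    domain_cache: dict[int, bool] = {}  # structural domain is per dictionary

    def eligible(node_id: str) -> bool:
        hyp = net.hypothesis(node_id)
        if hasattr(hyp, "fragments"):
            # share per-fragment match results across hypotheses
            ok = all(
                match_cache.setdefault(f.canonical_key, f.matches(query))
                for f in hyp.fragments
            )
            if not ok:
                return False
            key = id(hyp.dictionary)
            if key not in domain_cache:
                domain_cache[key] = hyp.in_domain(query)
            return domain_cache[key]
        return hyp.matches(query) and hyp.in_domain(query)

    eligible_ids = {n for n in net.graph.nodes if eligible(n)}
    result = [
        n for n in eligible_ids
        if not (nx.descendants(net.graph, n) & eligible_ids)
    ]
    return sorted(result)


def local_predict(
    hyp: Hypothesis,
    query: Molecule,
    dataset: ReferenceDataset,
    k: int = 10,
    similarity_exponent: float = 0.5,
    divide_by_k_used: bool = False,
) -> LocalPrediction:
    """kNN prediction from the hypothesis's supporting examples.

    Example hypotheses short-circuit to the factual data: an exact match is
    certain, so the local signal is the (uniform) mean of the instance
    signals of the identical reference structures, giving +/-1 when their
    labels agree.
    """
    stats = hyp.coverage(dataset)
    if stats.N == 0:
        raise ValueError(f"hypothesis {hyp.id!r} covers no examples")
    supporting = [dataset[i] for i in sorted(stats.coverage)]

    if hyp.kind == "EXAMPLE":
        neighbours = [
            Neighbour(e.id, 1.0, 1.0, e.instance_signal) for e in supporting
        ]
        signal = sum(n.instance_signal for n in neighbours) / len(neighbours)
        ws = signal
        k_used = len(neighbours)
    else:
        scored = sorted(
            supporting,
            key=lambda e: (-hyp.similarity(query, e.molecule), e.id),
        )
        nearest = scored[:k]
        neighbours = []
        for e in nearest:
            sim = hyp.similarity(query, e.molecule)
            neighbours.append(
                Neighbour(e.id, sim, sim ** similarity_exponent, e.instance_signal)
            )
        k_used = len(neighbours)
        weight_sum = sum(n.weight for n in neighbours)
        signal_sum = sum(n.weight * n.instance_signal for n in neighbours)
        ws = signal_sum / weight_sum if weight_sum > 0 else 0.0
        divisor = k_used if divide_by_k_used else k
        signal = signal_sum / divisor

    if signal > 0:
        predicted: Label | None = Label.POSITIVE
    elif signal < 0:
        predicted = Label.NEGATIVE
    else:
        predicted = None
    reference_signal = stats.signal(Label.POSITIVE)
    overruled = signal * reference_signal < 0
    return LocalPrediction(
        hypothesis_id=hyp.id,
        neighbours=neighbours,
        k_used=k_used,
        weighted_signal=ws,
        signal=signal,
        predicted_class=predicted,
        confidence=abs(signal),
        overruled=overruled,
    )


def global_predict(
    local_predictions: list[LocalPrediction],
    a: float = 0.0,
    b: float = 0.0,
    ignore_overruled: bool = False,
    query_id: str = "",
) -> GlobalPrediction:
    """Confidence-weighted overall call over the local predictions."""
    if not local_predictions:
        raise ValueError("at least one local prediction is required")
    if b < 0:
        raise ValueError("b must be >= 0")
    retained = [
        lp for lp in local_predictions if not (ignore_overruled and lp.overruled)
    ]
    conf_sum = sum(lp.confidence for lp in retained)
    if conf_sum > 0:
        s_x = sum(lp.signal * lp.confidence for lp in retained) / conf_sum
    else:
        s_x = 0.0  # all retained locals equivocal (or all dropped)
    if s_x > a + b:
        predicted: Label | None = Label.POSITIVE
    elif s_x < a - b:
        predicted = Label.NEGATIVE
    else:
        predicted = None
    return GlobalPrediction(
        query_id=query_id,
        relevant_hypotheses=[lp.hypothesis_id for lp in local_predictions],
        locals=local_predictions,
        overall_signal=s_x,
        a=a,
        b=b,
        predicted_class=predicted,
        raw_confidence=abs(s_x),
    )


@dataclass
class PredictConfig:
    k: int = 10
    a: float = 0.0
    b: float = 0.0
    similarity_exponent: float = 0.5
    divide_by_k_used: bool = False
    ignore_overruled: bool = False
    attach_paths: bool = True


def predict(
    net: SOHNNetwork,
    query: Molecule,
    calibration=None,
    config: PredictConfig | None = None,
) -> GlobalPrediction:
    """Full pipeline: relevant hypotheses -> local kNN -> overall call.

    ``calibration`` is an optional :class:`sohn.evaluate.CalibrationModel`
    mapping the raw confidence to the standard confidence; without it the
    raw value is reported unchanged.
    """
    config = config or PredictConfig()
    relevant = find_relevant_hypotheses(net, query)
    local_predictions = [
        local_predict(
            net.hypothesis(n), query, net.reference,
            k=config.k,
            similarity_exponent=config.similarity_exponent,
            divide_by_k_used=config.divide_by_k_used,
        )
        for n in relevant
    ]
    result = global_predict(
        local_predictions, a=config.a, b=config.b,
        ignore_overruled=config.ignore_overruled, query_id=query.id,
    )
    if calibration is not None:
        result.standard_confidence = float(calibration.transform(result.raw_confidence))
    else:
        result.standard_confidence = result.raw_confidence
    if config.attach_paths:
        result.sar_paths = {n: net.sar_paths(n) for n in relevant}
    return result


def format_prediction(result: GlobalPrediction, net: SOHNNetwork) -> str:
    """Human-readable prediction report."""
    cls = result.predicted_class.value if result.predicted_class else "EQUIVOCAL"
    lines = [
        f"query: {result.query_id}",
        f"class: {cls}",
        f"standard confidence: {result.standard_confidence:.3f}",
        f"hypotheses used (m={result.m}):",
    ]
    for lp in result.locals:
        hyp = net.hypothesis(lp.hypothesis_id)
        local_cls = lp.predicted_class.value if lp.predicted_class else "EQUIVOCAL"
        flag = " [overruled]" if lp.overruled else ""
        lines.append(
            f"  {lp.hypothesis_id}: {local_cls} "
            f"(confidence {lp.confidence:.3f}){flag} - {hyp.human_description}"
        )
        for nb in lp.neighbours[:5]:
            lines.append(
                f"    support {nb.example_id} similarity {nb.similarity:.3f} "
                f"({'+' if nb.instance_signal > 0 else '-'})"
            )
        for path in result.sar_paths.get(lp.hypothesis_id, [])[:3]:
            lines.append("    path: " + " -> ".join(path.node_ids))
    return "\n".join(lines)
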