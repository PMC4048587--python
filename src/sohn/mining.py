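"""Mining structural hypotheses by recursive partitioning on fragments.

Non-rare dictionary fragments become binary presence descriptors; a small
decision tree is grown by maximising Shannon information gain, and every
node reached through at least one presence edge is converted into a
structural hypothesis whose fragment conjunction is the set of fragments
asserted *present* along its path.  Absence branches contribute nothing to a
conjunction (a "fragment absent" clause is not an interpretable structural
alert), which guarantees that each emitted hypothesis covers a subset of
what its emitting ancestor covers.

The tree is a means of identifying information-rich fragments, not a final
model: the hypotheses it yields are re-evaluated against the full reference
dataset and filtered on coverage and signal before entering the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemio import Label, ReferenceDataset
from .fragmentation import FragmentDictionary
from .hypotheses import StructuralHypothesis


def build_descriptor_matrix(
    dataset: ReferenceDataset, dictionary: FragmentDictionary
) -> pd.DataFrame:
    """Boolean example x fragment presence matrix over non-rare fragments.

    Rows follow dataset order; columns are canonical keys in sorted order,
    so the matrix is deterministic for a fixed dataset and dictionary.
    """
    keys = dictionary.non_rare_keys()
    ids = dataset.ids
    data = np.zeros((len(ids), len(keys)), dtype=bool)
    for j, key in enumerate(keys):
        present = dictionary.presence[key]
        for i, ex_id in enumerate(ids):
            if ex_id in present:
                data[i, j] = True
    return pd.DataFrame(data, index=ids, columns=keys)


def _entropy(n_pos: float, n_neg: float) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    h = 0.0
    for c in (n_pos, n_neg):
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def information_gain(labels: np.ndarray, split: np.ndarray) -> float:
    """Shannon entropy gain (bits, base 2) of a boolean split of ``labels``.

    ``labels`` is a boolean array (True = positive); ``split`` partitions it
    into the True and False branches.
    """
    labels = np.asarray(labels, dtype=bool)
    split = np.asarray(split, dtype=bool)
    n = labels.size
    parent = _entropy(int(labels.sum()), int(n - labels.sum()))
    child = 0.0
    for branch in (split, ~split):
        nb = int(branch.sum())
        if nb == 0:
            continue
        pos = int(labels[branch].sum())
        child += nb / n * _entropy(pos, nb - pos)
    return parent - child


@dataclass
class TreeNode:
    example_ids: list[str]
    depth: int
    n_pos: int
    n_neg: int
    path_fragments: tuple[str, ...]  # fragments asserted present on the path
    split_fragment: str | None = None
    present_branch: "TreeNode | None" = None
    absent_branch: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_fragment is None

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.present_branch.walk()
            yield from self.absent_branch.walk()

    def structure_hash(self) -> str:
        """Stable hash of tree topology + splits, for determinism checks."""
        import hashlib

        parts = []
        for node in self.walk():
            parts.append(
                f"{node.depth}|{node.split_fragment}|{node.n_pos}|{node.n_neg}"
            )
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()[:16]


@dataclass
class MiningConfig:
    min_node_size: int = 4
    max_depth: int = 8
    min_gain: float = 0.0
    min_coverage: int = 4
    min_abs_signal: float = 0.0
    emit_mode: str = "path"  # "path" (conjunction) or "node" (last split only)


def grow_tree(
    matrix: pd.DataFrame,
    labels: dict[str, Label] | pd.Series,
    config: MiningConfig | None = None,
) -> TreeNode:
    """Grow the recursive-partitioning tree on presence descriptors.

    At each node the fragment maximising information gain is chosen, ties
    broken by lexicographically smaller canonical key.  Splitting stops on
    purity, node size below ``min_node_size``, ``max_depth``, or when the
    best gain does not exceed ``min_gain`` (a zero-gain split carries no
    information and is never made).
    """
    config = config or MiningConfig()
    if matrix.empty:
        raise ValueError("empty descriptor matrix")
    if isinstance(labels, pd.Series):
        label_map = {i: v for i, v in labels.items()}
    else:
        label_map = dict(labels)
    X = matrix.to_numpy(dtype=bool)
    cols = np.array(matrix.columns)
    y = np.array([label_map[i] is Label.POSITIVE for i in matrix.index], dtype=bool)
    ids = np.array(matrix.index)

    def build(rows: np.ndarray, depth: int, path: tuple[str, ...]) -> TreeNode:
        sub_y = y[rows]
        n_pos = int(sub_y.sum())
        n_neg = int(rows.size - n_pos)
        node = TreeNode(list(ids[rows]), depth, n_pos, n_neg, path)
        if (
            n_pos == 0
            or n_neg == 0
            or rows.size < config.min_node_size
            or depth >= config.max_depth
        ):
            return node
        sub_X = X[rows]
        n = rows.size
        t = sub_X.sum(axis=0).astype(float)              # examples with fragment
        tp = (sub_X & sub_y[:, None]).sum(axis=0).astype(float)
        parent = _entropy(n_pos, n_neg)

        def branch_entropy(pos, tot):
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(tot > 0, pos / np.maximum(tot, 1), 0.0)
                q = 1.0 - p
                h = -(
                    np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
                    + np.where(q > 0, q * np.log2(np.maximum(q, 1e-300)), 0.0)
                )
            return np.where(tot > 0, h, 0.0)

        gains = (
            parent
            - (t / n) * branch_entropy(tp, t)
            - ((n - t) / n) * branch_entropy(n_pos - tp, n - t)
        )
        # a split must separate something: both branches non-empty
        gains[(t == 0) | (t == n)] = -np.inf
        best_gain = gains.max()
        if not np.isfinite(best_gain) or best_gain < config.min_gain or best_gain <= 1e-12:
            return node
        candidates = np.flatnonzero(gains >= best_gain - 1e-12)
        j = candidates[np.argsort(cols[candidates])[0]]  # lexicographic tie-break
        key = str(cols[j])
        mask = sub_X[:, j]
        node.split_fragment = key
        node.present_branch = build(rows[mask], depth + 1, path + (key,))
        node.absent_branch = build(rows[~mask], depth + 1, path)
        return node

    return build(np.arange(len(ids)), 0, ())


def tree_to_hypotheses(
    tree: TreeNode,
    dictionary: FragmentDictionary,
    emit_mode: str = "path",
    id_prefix: str = "m",
) -> list[StructuralHypothesis]:
    """Convert tree nodes reached through >= 1 presence edge to hypotheses.

    ``path`` mode (default) emits the conjunction of all presence-path
    fragments; ``node`` mode emits only the most recent presence fragment.
    Duplicate fragment sets collapse to one hypothesis.
    """
    if emit_mode not in ("path", "node"):
        raise ValueError(f"unknown emit_mode {emit_mode!r}")
    seen: dict[tuple[str, ...], StructuralHypothesis] = {}
    for node in tree.walk():
        if not node.path_fragments:
            continue  # reached only through absence edges (or the root)
        if emit_mode == "path":
            keyset = tuple(sorted(set(node.path_fragments)))
        else:
            keyset = (node.path_fragments[-1],)
        if keyset in seen:
            continue
        frags = [dictionary.fragments[k] for k in keyset]
        hyp = StructuralHypothesis(
            f"{id_prefix}{len(seen):03d}", frags, dictionary=dictionary
        )
        seen[keyset] = hyp
    return list(seen.values())


def filter_hypotheses(
    hypotheses: list[StructuralHypothesis],
    dataset: ReferenceDataset,
    min_coverage: int = 4,
    min_abs_signal: float = 0.0,
) -> list[StructuralHypothesis]:
    """Retain hypotheses with N >= min_coverage and |signal| >= min_abs_signal;
    de-duplicate identical coverages keeping the shortest description."""
    kept: dict[frozenset[str], StructuralHypothesis] = {}
    for hyp in hypotheses:
        stats = hyp.coverage(dataset)
        if stats.N < min_coverage:
            continue
        if abs(stats.signal()) < min_abs_signal:
            continue
        prev = kept.get(stats.coverage)
        if prev is None or len(hyp.fragments) < len(prev.fragments):
            kept[stats.coverage] = hyp
    return list(kept.values())


def mine_hypotheses(
    dataset: ReferenceDataset,
    dictionary: FragmentDictionary,
    config: MiningConfig | None = None,
) -> list[StructuralHypothesis]:
    """Full mining workflow: descriptor matrix -> tree -> filtered hypotheses."""
    config = config or MiningConfig()
    matrix = build_descriptor_matrix(dataset, dictionary)
    labels = {e.id: e.label for e in dataset}
    tree = grow_tree(matrix, labels, config)
    hyps = tree_to_hypotheses(tree, dictionary, config.emit_mode)
    return filter_hypotheses(hyps, dataset, config.min_coverage, config.min_abs_signal)
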