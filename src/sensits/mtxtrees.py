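"""Multitask extremely randomized trees with task-splitting nodes.

An extremely randomized tree (extra-tree) draws K candidate features at each
node, one uniform-random threshold per feature, and keeps the candidate with
the largest Gini impurity decrease.  The multitask variant here trains one
forest over several related binary classification tasks at once — protein
binding (PB), keratinocyte activation (KA), dendritic-cell activation (DC)
and human skin sensitization (HUMAN) — by adding *task-split* candidates: at
every node holding two or more tasks, each task contributes a one-vs-rest
partition candidate that routes its own samples to one child and the rest to
the other.  Task splits compete with feature splits on the same impurity
criterion, so the forest learns shared structure where it helps and peels
tasks apart where it does not.

Prediction for a target task walks each tree: feature-split nodes test the
query fingerprint, task-split nodes follow the branch whose partition
contains the target task, and the leaf contributes its per-task positive
fraction (the pooled fraction when the target task never reached that leaf).
The forest score is the plain mean over trees, so it always lies in [0, 1].

Randomization protocol (mirrored by the single-task reference used in the
test suite, so it is part of the module contract): at each splittable node
the eligible features are the non-constant columns in ascending index order;
``k = min(k_features, len(eligible))`` of them are drawn via
``Generator.choice(eligible, size=k, replace=False)``; then, in draw order,
each candidate's threshold is ``Generator.uniform(col_min, col_max)``.
Task-split candidates are appended after the feature candidates (no RNG, task
ids in sorted order).  Ties on impurity decrease keep the first-generated
candidate.  One integer seed drives the whole forest through
``SeedSequence(seed).spawn(n_trees)``, one child stream per tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

TASKS = ("PB", "KA", "DC", "HUMAN")


@dataclass
class TaskDataset:
    """Stacked per-task training data: fingerprint rows, 0/1 labels, task ids."""

    features: np.ndarray   # (n, d) binary
    labels: np.ndarray     # (n,) in {0, 1}
    task_ids: np.ndarray   # (n,) strings

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.task_ids = np.asarray(self.task_ids, dtype=object)
        n = self.features.shape[0]
        if self.labels.shape[0] != n or self.task_ids.shape[0] != n:
            raise ValidationError("features, labels and task_ids must have equal row counts")
        if n == 0:
            raise ValidationError("empty dataset")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.task_ids)))


@dataclass
class MtParams:
    """Forest hyperparameters.

    ``k_features`` defaults to ceil(sqrt(d)) at fit time when left ``None``.
    """

    n_trees: int = 100
    k_features: Optional[int] = None
    min_samples_leaf: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.k_features is not None and self.k_features < 1:
            raise ValidationError("k_features must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValidationError("min_samples_leaf must be >= 1")


@dataclass
class MtNode:
    """One tree node: a feature split, a task split, or a leaf."""

    kind: str  # "feature_split" | "task_split" | "leaf"
    feature_index: Optional[int] = None
    threshold: Optional[float] = None
    tasks_left: Optional[frozenset] = None  # task_split: tasks routed left
    left: Optional["MtNode"] = None
    right: Optional["MtNode"] = None
    # leaf payload
    n_samples: int = 0
    pooled_fraction: Optional[float] = None
    task_fractions: dict = field(default_factory=dict)


@dataclass
class MtForest:
    """A trained multitask extra-trees ensemble."""

    trees: list[MtNode]
    params: MtParams
    fingerprint_width: int
    tasks: tuple[str, ...]


def _gini(pos: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = pos / n
    return 2.0 * p * (1.0 - p)


def _leaf(y: np.ndarray, t: np.ndarray) -> MtNode:
    n = y.shape[0]
    fractions = {}
    for task in np.unique(t):
        mask = t == task
        fractions[str(task)] = float(y[mask].mean())
    return MtNode(
        kind="leaf",
        n_samples=n,
        pooled_fraction=float(y.mean()),
        task_fractions=fractions,
    )


def _build_node(
    X: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
    k_features: int,
    min_samples_leaf: int,
) -> MtNode:
    n = y.shape[0]
    n_pos = int(y.sum())
    if n_pos in (0, n) or n < 2 * min_samples_leaf:
        return _leaf(y, t)

    col_min = X.min(axis=0)
    col_max = X.max(axis=0)
    eligible = np.flatnonzero(col_min < col_max)  # ascending index order
    present = sorted(set(t))

    candidates: list[tuple[str, object, np.ndarray]] = []
    if eligible.size:
        k = min(k_features, eligible.size)
        feats = rng.choice(eligible, size=k, replace=False)
        for f in feats:
            thr = rng.uniform(col_min[f], col_max[f])
            candidates.append(("feature_split", (int(f), float(thr)), X[:, f] <= thr))
    if len(present) >= 2:
        for task in present:
            candidates.append(("task_split", frozenset([task]), t == task))

    parent_gini = _gini(n_pos, n)
    best = None
    best_gain = 0.0
    for kind, payload, left_mask in candidates:
        nl = int(left_mask.sum())
        nr = n - nl
        if nl < min_samples_leaf or nr < min_samples_leaf:
            continue
        pos_l = int(y[left_mask].sum())
        gain = parent_gini - (nl / n) * _gini(pos_l, nl) - (nr / n) * _gini(n_pos - pos_l, nr)
        if best is None or gain > best_gain:
            best = (kind, payload, left_mask)
            best_gain = gain
    if best is None:
        return _leaf(y, t)

    kind, payload, left_mask = best
    left = _build_node(X[left_mask], y[left_mask], t[left_mask], rng, k_features, min_samples_leaf)
    right = _build_node(X[~left_mask], y[~left_mask], t[~left_mask], rng, k_features, min_samples_leaf)
    if kind == "feature_split":
        f, thr = payload
        return MtNode(kind=kind, feature_index=f, threshold=thr, left=left, right=right,
                      n_samples=n)
    return MtNode(kind=kind, tasks_left=payload, left=left, right=right, n_samples=n)


def fit(data: TaskDataset, params: Optional[MtParams] = None) -> MtForest:
    """Train a multitask extra-trees forest.

    Deterministic given ``params.rng_seed``.  A dataset where every task is
    single-class still trains (to trivial pure leaves); an empty dataset is a
    validation error raised by :class:`TaskDataset`.
    """
    if params is None:
        params = MtParams()
    d = data.features.shape[1]
    k = params.k_features if params.k_features is not None else int(np.ceil(np.sqrt(d)))
    streams = np.random.SeedSequence(params.rng_seed).spawn(params.n_trees)
    trees = [
        _build_node(
            data.features, data.labels, data.task_ids,
            np.random.default_rng(ss), k, params.min_samples_leaf,
        )
        for ss in streams
    ]
    return MtForest(trees=trees, params=params, fingerprint_width=d, tasks=data.tasks)


def _tree_score(node: MtNode, x: np.ndarray, task: str) -> float:
    while node.kind != "leaf":
        if node.kind == "feature_split":
            node = node.left if x[node.feature_index] <= node.threshold else node.right
        else:
            node = node.left if task in node.tasks_left else node.right
    if task in node.task_fractions:
        return node.task_fractions[task]
    return node.pooled_fraction


def predict(forest: MtForest, features: np.ndarray, task: str) -> float | np.ndarray:
    """Score one fingerprint (1-D) or a stack of them (2-D) for ``task``.

    The score is the mean over trees of the leaf estimate for the requested
    task and always lies in [0, 1].
    """
    if task not in forest.tasks:
        raise ValidationError(f"task {task!r} not present in training ({forest.tasks})")
    x = np.asarray(features)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != forest.fingerprint_width:
        raise ValidationError(
            f"feature length {X.shape[1]} != fingerprint width {forest.fingerprint_width}"
        )
    scores = np.array(
        [np.mean([_tree_score(tree, row, task) for tree in forest.trees]) for row in X]
    )
    return float(scores[0]) if single else scores


def concatenate(forests: Sequence[MtForest]) -> MtForest:
    """Merge forests over the same feature space into one larger ensemble."""
    widths = {f.fingerprint_width for f in forests}
    if len(widths) != 1:
        raise ValidationError("forests span different feature spaces")
    trees = [t for f in forests for t in f.trees]
    tasks = tuple(sorted(set().union(*(f.tasks for f in forests))))
    return MtForest(trees=trees, params=forests[0].params,
                    fingerprint_width=widths.pop(), tasks=tasks)


# --- JSON serialization -----------------------------------------------------

def _node_to_dict(node: MtNode) -> dict:
    if node.kind == "leaf":
        return {
            "kind": "leaf",
            "n_samples": node.n_samples,
            "pooled_fraction": node.pooled_fraction,
            "task_fractions": node.task_fractions,
        }
    out = {
        "kind": node.kind,
        "n_samples": node.n_samples,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }
    if node.kind == "feature_split":
        out["feature_index"] = node.feature_index
        out["threshold"] = node.threshold
    else:
        out["tasks_left"] = sorted(node.tasks_left)
    return out


def _node_from_dict(d: dict) -> MtNode:
    if d["kind"] == "leaf":
        return MtNode(
            kind="leaf",
            n_samples=d["n_samples"],
            pooled_fraction=d["pooled_fraction"],
            task_fractions=dict(d["task_fractions"]),
        )
    return MtNode(
        kind=d["kind"],
        feature_index=d.get("feature_index"),
        threshold=d.get("threshold"),
        tasks_left=frozenset(d["tasks_left"]) if "tasks_left" in d else None,
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
        n_samples=d["n_samples"],
    )


def to_json(forest: MtForest, path=None) -> str:
    """Serialize a forest to the documented nested-record JSON structure."""
    doc = {
        "format": "sensits-mtforest/1",
        "fingerprint_width": forest.fingerprint_width,
        "tasks": list(forest.tasks),
        "params": {
            "n_trees": forest.params.n_trees,
            "k_features": forest.params.k_features,
            "min_samples_leaf": forest.params.min_samples_leaf,
            "rng_seed": forest.params.rng_seed,
        },
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source) -> MtForest:
    """Load a forest written by :func:`to_json` (path or JSON string)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    params = MtParams(**doc["params"])
    return MtForest(
        trees=[_node_from_dict(t) for t in doc["trees"]],
        params=params,
        fingerprint_width=doc["fingerprint_width"],
        tasks=tuple(doc["tasks"]),
    )


def read_training_table(path, n_bits: int = 1024) -> TaskDataset:
    """Read a ``smiles,task,label`` CSV into a TaskDataset (fingerprints computed)."""
    import pandas as pd

    from .chemio import parse_molecule
    from .errors import SchemaError

    df = pd.read_csv(path)
    missing = [c for c in ("smiles", "task", "label") if c not in df.columns]
    if missing:
        raise SchemaError(missing, str(path))
    fps = np.stack([parse_molecule(s, n_bits=n_bits).fingerprint for s in df["smiles"]])
    return TaskDataset(
        features=fps,
        labels=df["label"].to_numpy(),
        task_ids=df["task"].to_numpy(),
    )
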