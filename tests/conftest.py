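"""Shared independent oracles for the test suite.

These re-derive expected behavior by brute force or by an independent
re-implementation, and are deliberately kept separate from the library code
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- exhaustive ITS completion oracle --------------------------------------

def brute_force_classify(dpra, hclat, insilico):
    """Classify by enumerating every completion of missing component scores.

    Returns (hazard, potency); a verdict is conclusive only when all
    completions agree, otherwise "inconclusive".
    """
    d_opts = [dpra] if dpra is not None else list(range(4))
    h_opts = [hclat] if hclat is not None else list(range(4))
    i_opts = [insilico] if insilico is not None else [0, 1]
    hazards, potencies = set(), set()
    for d, h, i in itertools.product(d_opts, h_opts, i_opts):
        total = d + h + i
        hazards.add("sensitizer" if total >= 2 else "not_classified")
        if total >= 6:
            potencies.add("1A")
        elif total >= 2:
            potencies.add("1B")
        else:
            potencies.add("NC")
    hazard = hazards.pop() if len(hazards) == 1 else "inconclusive"
    potency = potencies.pop() if len(potencies) == 1 else "inconclusive"
    return hazard, potency


def all_score_combinations():
    """All 5 x 5 x 3 = 75 (dpra, hclat, insilico) combinations with missing."""
    return list(
        itertools.product(
            [None, 0, 1, 2, 3], [None, 0, 1, 2, 3], [None, 0, 1]
        )
    )


# --- naive per-item metric recount ------------------------------------------

def naive_hazard_recount(predicted, truth):
    """Per-item recount of confusion cells and Eq.-style rates, loop based."""
    tp = tn = fp = fn = inc = 0
    for p, t in zip(predicted, truth):
        truth_pos = t in ("sensitizer", "1A", "1B")
        if p == "inconclusive":
            inc += 1
        elif p in ("sensitizer", "1A", "1B"):
            tp, fp = (tp + 1, fp) if truth_pos else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if truth_pos else (fn, tn + 1)
    n_conc = tp + tn + fp + fn
    out = {"tp": tp, "tn": tn, "fp": fp, "fn": fn,
           "coverage": 100.0 * n_conc / len(predicted) if predicted else 0.0}
    out["sensitivity"] = 100.0 * tp / (tp + fn) if tp + fn else None
    out["specificity"] = 100.0 * tn / (tn + fp) if tn + fp else None
    out["accuracy"] = 100.0 * (tp + tn) / n_conc if n_conc else None
    return out


# --- independent single-task extra-trees -------------------------------------

def _gini(pos, n):
    if n == 0:
        return 0.0
    p = pos / n
    return 2.0 * p * (1.0 - p)


def oracle_build_tree(X, y, rng, k_features, min_samples_leaf):
    """Plain (single-task) extra-tree following the documented randomization
    protocol: sorted eligible features, Generator.choice without replacement,
    one uniform threshold per candidate, best Gini gain wins, first-generated
    wins ties."""
    n = y.shape[0]
    pos = int(y.sum())
    if pos in (0, n) or n < 2 * min_samples_leaf:
        return ("leaf", float(y.mean()), n)
    col_min, col_max = X.min(axis=0), X.max(axis=0)
    eligible = np.flatnonzero(col_min < col_max)
    candidates = []
    if eligible.size:
        feats = rng.choice(eligible, size=min(k_features, eligible.size), replace=False)
        for f in feats:
            thr = rng.uniform(col_min[f], col_max[f])
            candidates.append((int(f), float(thr), X[:, f] <= thr))
    parent = _gini(pos, n)
    best, best_gain = None, 0.0
    for f, thr, mask in candidates:
        nl = int(mask.sum())
        nr = n - nl
        if nl < min_samples_leaf or nr < min_samples_leaf:
            continue
        pl = int(y[mask].sum())
        gain = parent - (nl / n) * _gini(pl, nl) - (nr / n) * _gini(pos - pl, nr)
        if best is None or gain > best_gain:
            best, best_gain = (f, thr, mask), gain
    if best is None:
        return ("leaf", float(y.mean()), n)
    f, thr, mask = best
    return (
        "split", f, thr,
        oracle_build_tree(X[mask], y[mask], rng, k_features, min_samples_leaf),
        oracle_build_tree(X[~mask], y[~mask], rng, k_features, min_samples_leaf),
    )


def oracle_tree_predict(node, x):
    while node[0] == "split":
        _, f, thr, left, right = node
        node = left if x[f] <= thr else right
    return node[1]


def oracle_fit_forest(X, y, n_trees, k_features, min_samples_leaf, seed):
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    return [
        oracle_build_tree(X, y, np.random.default_rng(ss), k_features, min_samples_leaf)
        for ss in streams
    ]


def oracle_forest_predict(trees, x):
    return float(np.mean([oracle_tree_predict(t, x) for t in trees]))
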