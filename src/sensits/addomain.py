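"""Applicability domains: the pesticide exclusion ruleset and the original-domain check.

A quantitative structure-activity model is only trusted inside its
applicability domain (AD).  Two domains are implemented:

* **Pesticide AD** — a consensus chemical space for pesticide nonsensitizers.
  A classification tree (CART) is fitted on fingerprint bits with the target
  "does the in silico call disagree with the animal-test call?".  Every
  root-to-leaf path whose leaf is sufficiently enriched in discordant
  molecules becomes an *exclusion rule*: a conjunction of fingerprint-bit
  conditions identifying structure characteristics the model gets wrong.  A
  molecule matching any rule is out of domain, and each out-of-domain verdict
  can cite the rule that produced it.

* **Original AD** — an unseen-feature check: a molecule is in domain iff
  every structural feature (set fingerprint bit) it carries was seen in at
  least one training molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .chemio import Molecule
from .errors import ValidationError


@dataclass(frozen=True)
class ExclusionRule:
    """Conjunction of fingerprint-bit conditions marking out-of-domain structures.

    ``conditions`` is a tuple of ``(bit_index, required_value)`` pairs; an
    empty tuple (the degenerate root-level rule, arising when every training
    record is discordant) matches every molecule.
    """

    conditions: tuple[tuple[int, int], ...]
    support: int
    discordant_fraction: float

    def __post_init__(self):
        seen: dict[int, int] = {}
        for bit, val in self.conditions:
            if val not in (0, 1):
                raise ValidationError(f"rule condition value {val} not 0/1")
            if seen.setdefault(bit, val) != val:
                raise ValidationError(f"contradictory conditions on bit {bit}")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValidationError("discordant_fraction outside [0, 1]")

    def matches(self, fingerprint: np.ndarray) -> bool:
        return all(int(fingerprint[bit]) == val for bit, val in self.conditions)


@dataclass
class AdRuleset:
    """Pesticide-mode exclusion ruleset: out-of-domain iff >= 1 rule matches."""

    rules: list[ExclusionRule]
    mode: str = "pesticide"
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConcordanceRecord:
    """One pesticide with its in silico call and the matched animal-test call."""

    molecule: Molecule
    insilico_call: str      # "positive" | "negative"
    animal_call: str        # "positive" | "negative"
    pesticide_class: str = "herbicide"  # herbicide | fungicide | insecticide

    def __post_init__(self):
        for name, value in (("insilico_call", self.insilico_call),
                            ("animal_call", self.animal_call)):
            if value not in ("positive", "negative"):
                raise ValidationError(f"{name} must be positive/negative, got {value!r}")

    @property
    def discordant(self) -> bool:
        return self.insilico_call != self.animal_call


@dataclass
class AdParams:
    """CART settings for rule derivation (shallow trees keep rules interpretable)."""

    max_depth: int = 4
    min_samples_leaf: int = 5
    purity_threshold: float = 0.8  # minimum leaf discordant fraction for a rule
    random_state: int = 0


def derive_pesticide_ad(
    records: Sequence[ConcordanceRecord], params: Optional[AdParams] = None
) -> AdRuleset:
    """Derive the pesticide exclusion ruleset from prediction/animal discordance.

    Fits a Gini CART on fingerprint bits with target discordant(1) vs
    concordant(0) and converts every root-to-leaf path whose leaf reaches
    ``purity_threshold`` discordant fraction into an :class:`ExclusionRule`.
    With no discordant records the ruleset is empty (everything in domain).
    """
    if params is None:
        params = AdParams()
    if len(records) < 2:
        raise ValidationError("need at least 2 concordance records")
    X = np.stack([r.molecule.fingerprint for r in records]).astype(np.float32)
    y = np.array([int(r.discordant) for r in records])
    provenance = {
        "n_records": len(records),
        "n_discordant": int(y.sum()),
        "max_depth": params.max_depth,
        "min_samples_leaf": params.min_samples_leaf,
        "purity_threshold": params.purity_threshold,
    }
    if y.sum() == 0:
        return AdRuleset(rules=[], provenance=provenance)

    cart = DecisionTreeClassifier(
        criterion="gini",
        max_depth=params.max_depth,
        min_samples_leaf=params.min_samples_leaf,
        random_state=params.random_state,
    )
    cart.fit(X, y)
    tree = cart.tree_
    # class order in tree_.value follows cart.classes_
    disc_col = int(np.flatnonzero(cart.classes_ == 1)[0]) if 1 in cart.classes_ else None

    rules: list[ExclusionRule] = []

    def walk(node: int, path: tuple[tuple[int, int], ...]):
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:  # leaf
            n = int(tree.n_node_samples[node])
            value = tree.value[node][0]  # per-class counts or fractions, ratio is the same
            frac = float(value[disc_col] / value.sum()) if disc_col is not None else 0.0
            if frac >= params.purity_threshold:
                # drop repeated conditions on the same bit (consistent by construction)
                dedup = tuple(dict(path).items())
                rules.append(ExclusionRule(conditions=dedup, support=n,
                                           discordant_fraction=frac))
            return
        bit = int(tree.feature[node])
        # binary features: x <= 0.5 means bit 0, x > 0.5 means bit 1
        walk(left, path + ((bit, 0),))
        walk(right, path + ((bit, 1),))

    walk(0, ())
    return AdRuleset(rules=rules, provenance=provenance)


def in_domain(mol: Molecule, ruleset: AdRuleset) -> bool:
    """Pesticide-AD membership: False iff the molecule matches an exclusion rule."""
    return matching_rule(mol, ruleset) is None


def matching_rule(mol: Molecule, ruleset: AdRuleset) -> Optional[ExclusionRule]:
    """First exclusion rule the molecule matches, for audit trails; None if in domain."""
    for rule in ruleset.rules:
        if rule.matches(mol.fingerprint):
            return rule
    return None


def in_original_domain(mol: Molecule, training_fingerprints: np.ndarray) -> bool:
    """Original-AD membership: every set bit of ``mol`` was seen in training."""
    fps = np.atleast_2d(np.asarray(training_fingerprints))
    if fps.size == 0 or fps.shape[0] == 0:
        raise ValidationError("empty training fingerprint set")
    seen = fps.max(axis=0).astype(bool)
    return bool(np.all(seen[mol.fingerprint.astype(bool)]))


# --- serialization ----------------------------------------------------------

def ruleset_to_json(ruleset: AdRuleset, path=None) -> str:
    doc = {
        "format": "sensits-adruleset/1",
        "mode": ruleset.mode,
        "provenance": ruleset.provenance,
        "rules": [
            {
                "conditions": [[int(b), int(v)] for b, v in r.conditions],
                "support": r.support,
                "discordant_fraction": r.discordant_fraction,
            }
            for r in ruleset.rules
        ],
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def ruleset_from_json(source) -> AdRuleset:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    rules = [
        ExclusionRule(
            conditions=tuple((int(b), int(v)) for b, v in r["conditions"]),
            support=int(r["support"]),
            discordant_fraction=float(r["discordant_fraction"]),
        )
        for r in doc["rules"]
    ]
    return AdRuleset(rules=rules, mode=doc.get("mode", "pesticide"),
                     provenance=doc.get("provenance", {}))
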