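"""Formulation-level evaluation: aggregate ingredient calls, assemble the ITS result.

DPRA and h-CLAT are measured on the formulation itself, but the in silico
component is computed per active ingredient and aggregated:

* *positive* if any ingredient is called positive at a concentration of at
  least 0.1 % w/w,
* otherwise *inconclusive* if any ingredient cannot be predicted (undefined
  structure or out of domain) while every predictable one is negative,
* otherwise *negative*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import addomain, itscore, mtxtrees
from .chemio import AssayPanel, Formulation, Ingredient
from .errors import ValidationError
from .itscore import InSilicoCall, ItsResult

POSITIVE_CONCENTRATION_CUTOFF = 0.1  # % w/w; inclusive


@dataclass
class FormulationCall:
    """Per-ingredient in silico calls and their formulation-level aggregate."""

    formulation_id: str
    ingredient_calls: list[tuple[Ingredient, InSilicoCall]]
    aggregate: str  # "positive" | "negative" | "inconclusive"


def aggregate_insilico(
    calls: Sequence[tuple[Ingredient, InSilicoCall]],
    concentration_cutoff: float = POSITIVE_CONCENTRATION_CUTOFF,
) -> str:
    """Aggregate ingredient-level in silico calls to one formulation verdict.

    A sub-cutoff positive ingredient neither triggers a positive verdict nor
    inconclusiveness; it falls into the residual *negative* branch.
    """
    if not calls:
        raise ValidationError("cannot aggregate an empty ingredient list")
    if any(
        call.call == "positive" and ing.concentration >= concentration_cutoff
        for ing, call in calls
    ):
        return "positive"
    predictable = [call.call for _, call in calls if call.call != "missing"]
    has_missing = len(predictable) < len(calls)
    if has_missing and all(c == "negative" for c in predictable):
        return "inconclusive"
    return "negative"


def call_ingredient(
    ingredient: Ingredient,
    model: Optional[mtxtrees.MtForest],
    mode: str = "pesticide",
    ad_ruleset: Optional[addomain.AdRuleset] = None,
    training_fingerprints: Optional[np.ndarray] = None,
    task: str = "HUMAN",
) -> InSilicoCall:
    """In silico call for one ingredient (missing for undefined structures)."""
    if ingredient.molecule is None or model is None:
        return InSilicoCall(score=None, mode=mode, in_domain=False, call="missing")
    mol = ingredient.molecule
    if mode == "pesticide":
        inside = ad_ruleset is None or addomain.in_domain(mol, ad_ruleset)
    else:
        inside = training_fingerprints is None or addomain.in_original_domain(
            mol, training_fingerprints
        )
    score = mtxtrees.predict(model, mol.fingerprint, task)
    return itscore.call_insilico(score, mode=mode, in_domain=inside)


def formulation_insilico(
    formulation: Formulation,
    model: Optional[mtxtrees.MtForest] = None,
    mode: str = "pesticide",
    ad_ruleset: Optional[addomain.AdRuleset] = None,
    training_fingerprints: Optional[np.ndarray] = None,
) -> FormulationCall:
    calls = [
        (ing, call_ingredient(ing, model, mode, ad_ruleset, training_fingerprints))
        for ing in formulation.ingredients
    ]
    return FormulationCall(
        formulation_id=formulation.id,
        ingredient_calls=calls,
        aggregate=aggregate_insilico(calls),
    )


def _aggregate_to_score(aggregate: str) -> Optional[int]:
    return {"positive": 1, "negative": 0}.get(aggregate)


def evaluate_formulation(
    formulation: Optional[Formulation],
    assays: AssayPanel,
    model: Optional[mtxtrees.MtForest] = None,
    mode: str = "pesticide",
    ad_ruleset: Optional[addomain.AdRuleset] = None,
    training_fingerprints: Optional[np.ndarray] = None,
) -> ItsResult:
    """Full ITS evaluation of one formulation.

    The in silico component comes from a precomputed ``insilico_call`` on the
    assay panel when present, else from per-ingredient model predictions
    aggregated by :func:`aggregate_insilico`.  Absent assay measurements
    leave the corresponding component missing, which propagates to the
    range-based inconclusive rule.
    """
    dpra_score = itscore.score_dpra(assays.dpra) if assays.dpra is not None else None
    hclat_score = itscore.score_hclat(assays.hclat) if assays.hclat is not None else None

    if assays.insilico_call is not None:
        insilico_score = _aggregate_to_score(assays.insilico_call)
    elif formulation is not None:
        fc = formulation_insilico(formulation, model, mode, ad_ruleset, training_fingerprints)
        insilico_score = _aggregate_to_score(fc.aggregate)
    else:
        insilico_score = None

    return itscore.combine_and_classify(dpra_score, hclat_score, insilico_score)
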