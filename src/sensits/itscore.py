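"""ITS scoring engine: assay binning, in silico call, combined hazard/potency classification.

The integrated testing strategy (ITS) turns three information sources into one
additive score:

* DPRA (direct peptide reactivity assay, key event 1) — scored 0-3 from the
  mean percent depletion of the cysteine and lysine peptides (cysteine-only
  bins when lysine co-elutes with the test substance),
* h-CLAT (human cell line activation test, key event 3) — scored 0-3 from the
  minimum induction threshold (MIT, ug/mL; lower MIT = stronger sensitizer),
* an in silico hazard call — scored 0/1, gated by an applicability domain.

The total (0-7) classifies hazard (>= 2 sensitizer, <= 1 not classified) and
GHS potency (6-7 -> 1A, 2-5 -> 1B, <= 1 -> NC).  A missing or out-of-domain
component widens the attainable total to a range; whenever that range straddles
a cutoff the verdict is *inconclusive* rather than a guess.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

# Score-bin boundaries (left-closed: a value equal to a boundary earns the
# higher score).  Kept in one place so alternative conventions are one edit
# away.  Depletions in percent, MIT in ug/mL.
DPRA_MEAN_DEPLETION_BINS = (6.38, 22.62, 42.47)
DPRA_CYS_ONLY_BINS = (13.89, 23.09, 98.24)  # used when lysine co-elutes
# MIT bins are right-closed on the upper end: MIT <= 10 -> 3, 10 < MIT <= 150
# -> 2, 150 < MIT <= 5000 -> 1, MIT > 5000 or negative outcome -> 0.
HCLAT_MIT_BINS = (10.0, 150.0, 5000.0)

INSILICO_NEGATIVE_CUTOFF = 0.4  # pesticide mode: score <= 0.4 in-domain -> nonsensitizer
INSILICO_POSITIVE_CUTOFF = 0.5  # non-pesticide mode: score >= 0.5 -> sensitizer

HAZARD_SENSITIZER_MIN = 2   # total 2-7 -> skin sensitizer
POTENCY_1A_MIN = 6          # total 6-7 -> GHS Category 1A
POTENCY_1B_MIN = 2          # total 2-5 -> GHS Category 1B

MAX_ASSAY_SCORE = 3
MAX_INSILICO_SCORE = 1


@dataclass(frozen=True)
class DpraResult:
    """DPRA outcome for one substance or formulation.

    Depletions are percentages in [-100, 100]; small negatives occur
    experimentally and are floored at 0 for binning.  ``lys_coelution`` marks
    co-elution of the lysine peptide with the test substance, in which case
    the cysteine-only scoring scheme applies.
    """

    cys_depletion: float
    lys_depletion: Optional[float] = None
    lys_coelution: bool = False

    @property
    def mean_depletion(self) -> Optional[float]:
        """Mean of cysteine and lysine depletion (negatives floored at 0).

        Defined only when the lysine measurement is valid (present and not
        co-eluting).
        """
        if self.lys_coelution or self.lys_depletion is None:
            return None
        return (max(self.cys_depletion, 0.0) + max(self.lys_depletion, 0.0)) / 2.0


@dataclass(frozen=True)
class HclatResult:
    """h-CLAT outcome: the MIT in ug/mL, or ``None`` for a negative outcome."""

    mit: Optional[float] = None

    @property
    def negative(self) -> bool:
        return self.mit is None


@dataclass(frozen=True)
class InSilicoCall:
    """In silico hazard call with its applicability-domain gating.

    ``call`` is ``"missing"`` whenever the score is absent or the molecule is
    outside the relevant applicability domain.
    """

    score: Optional[float]
    mode: str  # "pesticide" | "non_pesticide"
    in_domain: bool
    call: str  # "positive" | "negative" | "missing"

    @property
    def its_score(self) -> Optional[int]:
        if self.call == "positive":
            return 1
        if self.call == "negative":
            return 0
        return None


@dataclass(frozen=True)
class ItsResult:
    """Combined ITS outcome for one substance or formulation."""

    dpra_score: Optional[int]
    hclat_score: Optional[int]
    insilico_score: Optional[int]
    total_min: int
    total_max: int
    hazard: str   # "sensitizer" | "not_classified" | "inconclusive"
    potency: str  # "1A" | "1B" | "NC" | "inconclusive"
    components: dict = field(default_factory=dict)

    @property
    def conclusive_hazard(self) -> bool:
        return self.hazard != "inconclusive"

    @property
    def conclusive_potency(self) -> bool:
        return self.potency != "inconclusive"


def _check_depletion(value: float, name: str) -> float:
    if not -100.0 <= value <= 100.0:
        raise ValidationError(f"{name} depletion {value}% outside [-100, 100]")
    return max(value, 0.0)


def score_dpra(result: DpraResult) -> int:
    """Score a DPRA result 0-3.

    Without lysine co-elution the mean cysteine/lysine depletion is binned at
    6.38 / 22.62 / 42.47 %; with co-elution the cysteine-only depletion is
    binned at 13.89 / 23.09 / 98.24 %.  Bins are left-closed, so a depletion
    exactly at a boundary earns the higher score.  Negative depletions are
    treated as 0 %.
    """
    cys = _check_depletion(result.cys_depletion, "cysteine")
    if result.lys_coelution:
        return sum(cys >= b for b in DPRA_CYS_ONLY_BINS)
    if result.lys_depletion is None:
        raise ValidationError(
            "lysine depletion absent without co-elution; mean depletion undefined"
        )
    lys = _check_depletion(result.lys_depletion, "lysine")
    mean = (cys + lys) / 2.0
    # left-closed bins: count boundaries <= mean
    return sum(mean >= b for b in DPRA_MEAN_DEPLETION_BINS)


def score_hclat(result: HclatResult) -> int:
    """Score an h-CLAT result 0-3 from the minimum induction threshold.

    Negative outcome (no induction) scores 0; MIT > 5000 ug/mL is likewise
    treated as negative.  Bins are inclusive on the upper end: MIT <= 10 -> 3,
    10 < MIT <= 150 -> 2, 150 < MIT <= 5000 -> 1.
    """
    if result.negative:
        return 0
    mit = result.mit
    if mit is None or mit <= 0:
        raise ValidationError(f"h-CLAT MIT must be a positive number, got {mit!r}")
    if mit > HCLAT_MIT_BINS[-1]:
        return 0
    return MAX_ASSAY_SCORE - bisect.bisect_left(HCLAT_MIT_BINS, mit)


def call_insilico(
    score: Optional[float],
    mode: str = "pesticide",
    in_domain: bool = True,
    negative_cutoff: float = INSILICO_NEGATIVE_CUTOFF,
    positive_cutoff: float = INSILICO_POSITIVE_CUTOFF,
) -> InSilicoCall:
    """Turn a model score into a positive/negative/missing in silico call.

    Pesticide mode trusts the pesticide applicability domain: outside it the
    call is missing; inside it, score <= ``negative_cutoff`` (0.4) is a
    nonsensitizer and anything above is a sensitizer.  Non-pesticide mode uses
    the original applicability domain and the conventional 0.5 cutoff.
    """
    if mode not in ("pesticide", "non_pesticide"):
        raise ValidationError(f"unknown in silico mode {mode!r}")
    if score is not None and not 0.0 <= score <= 1.0:
        raise ValidationError(f"in silico score {score} outside [0, 1]")
    if score is None or not in_domain:
        return InSilicoCall(score=score, mode=mode, in_domain=in_domain, call="missing")
    if mode == "pesticide":
        call = "negative" if score <= negative_cutoff else "positive"
    else:
        call = "positive" if score >= positive_cutoff else "negative"
    return InSilicoCall(score=score, mode=mode, in_domain=in_domain, call=call)


def _check_component(value: Optional[int], name: str, upper: int) -> Optional[int]:
    if value is None:
        return None
    if not isinstance(value, (int,)) or not 0 <= value <= upper:
        raise ValidationError(f"{name} score {value!r} outside 0..{upper}")
    return value


def classify_total(total: int) -> tuple[str, str]:
    """Hazard and potency class of a fully known total score (0-7)."""
    hazard = "sensitizer" if total >= HAZARD_SENSITIZER_MIN else "not_classified"
    if total >= POTENCY_1A_MIN:
        potency = "1A"
    elif total >= POTENCY_1B_MIN:
        potency = "1B"
    else:
        potency = "NC"
    return hazard, potency


def combine_and_classify(
    dpra: Optional[int],
    hclat: Optional[int],
    insilico: Optional[int],
) -> ItsResult:
    """Sum component scores and classify hazard and GHS potency.

    A missing component widens the total to a range (missing assay adds 0-3,
    missing in silico call adds 0-1).  Hazard is *sensitizer* when every
    completion of the missing scores reaches 2, *not_classified* when none
    can, and *inconclusive* otherwise; potency works the same way over the
    NC / 1B / 1A cut points.  All three components missing is a valid input
    and yields inconclusive verdicts.
    """
    dpra = _check_component(dpra, "DPRA", MAX_ASSAY_SCORE)
    hclat = _check_component(hclat, "h-CLAT", MAX_ASSAY_SCORE)
    insilico = _check_component(insilico, "in silico", MAX_INSILICO_SCORE)

    total_min = sum(v for v in (dpra, hclat, insilico) if v is not None)
    total_max = total_min
    for v, width in ((dpra, MAX_ASSAY_SCORE), (hclat, MAX_ASSAY_SCORE),
                     (insilico, MAX_INSILICO_SCORE)):
        if v is None:
            total_max += width

    if total_min >= HAZARD_SENSITIZER_MIN:
        hazard = "sensitizer"
    elif total_max < HAZARD_SENSITIZER_MIN:
        hazard = "not_classified"
    else:
        hazard = "inconclusive"

    if total_min >= POTENCY_1A_MIN:
        potency = "1A"
    elif total_min >= POTENCY_1B_MIN and total_max < POTENCY_1A_MIN:
        potency = "1B"
    elif total_max < POTENCY_1B_MIN:
        potency = "NC"
    else:
        potency = "inconclusive"

    return ItsResult(
        dpra_score=dpra,
        hclat_score=hclat,
        insilico_score=insilico,
        total_min=total_min,
        total_max=total_max,
        hazard=hazard,
        potency=potency,
    )
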