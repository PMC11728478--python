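"""Benchmark metrics: hazard confusion rates and potency classification rates.

Hazard identification is scored with sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/(TP+TN+FP+FN) and balanced accuracy
(sensitivity+specificity)/2, all over *conclusive* predictions only.
Coverage is the fraction of substances for which a conclusive prediction
could be made at all.  Potency classification is scored over the GHS
ordering NC < 1B < 1A: exact matches are correct, a predicted class strictly
below the in vivo class is underpredicted, strictly above is overpredicted.
All rates are percentages at full float precision; round for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from sklearn.metrics import confusion_matrix

from .errors import ValidationError

POTENCY_ORDER = {"NC": 0, "1B": 1, "1A": 2}
_POSITIVE_HAZARDS = {"sensitizer", "positive"}
_NEGATIVE_HAZARDS = {"not_classified", "nonsensitizer", "negative", "NC"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_conclusive(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Hazard and/or potency rates, as percentages; None when undefined."""

    n_total: int
    n_conclusive: int
    coverage: float
    counts: Optional[ConfusionCounts] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None
    balanced_accuracy: Optional[float] = None
    potency_correct: Optional[float] = None
    potency_under: Optional[float] = None
    potency_over: Optional[float] = None


def _as_binary(value: str, kind: str) -> Optional[int]:
    if value == "inconclusive":
        return None
    if value in _POSITIVE_HAZARDS or value in ("1A", "1B"):
        return 1
    if value in _NEGATIVE_HAZARDS:
        return 0
    raise ValidationError(f"unrecognized {kind} value {value!r}")


def hazard_metrics(predicted: Sequence[str], truth: Sequence[str]) -> MetricsReport:
    """Confusion-based hazard rates over conclusive predictions plus coverage.

    ``predicted`` entries are hazard calls (``sensitizer`` /
    ``not_classified`` / ``inconclusive``; potency classes are accepted and
    collapsed to hazard).  ``truth`` entries are binary sensitizer /
    nonsensitizer labels (GHS 1A and 1B both count as sensitizer).
    Inconclusive predictions are excluded from the confusion counts but kept
    in the coverage denominator.  A rate whose denominator is zero is
    reported as None, not as 0.
    """
    if len(predicted) != len(truth):
        raise ValidationError("predicted and truth lengths differ")
    n_total = len(predicted)
    pairs = [
        (_as_binary(p, "prediction"), _as_binary(t, "truth"))
        for p, t in zip(predicted, truth)
    ]
    if any(t is None for _, t in pairs):
        raise ValidationError("truth labels must be conclusive")
    conclusive = [(p, t) for p, t in pairs if p is not None]
    n_conclusive = len(conclusive)
    coverage = 100.0 * n_conclusive / n_total if n_total else 0.0
    if not conclusive:
        return MetricsReport(n_total=n_total, n_conclusive=0, coverage=coverage)

    y_pred = [p for p, _ in conclusive]
    y_true = [t for _, t in conclusive]
    tn, fp, fn, tp = (int(v) for v in confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel())
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    acc = 100.0 * (tp + tn) / n_conclusive
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return MetricsReport(
        n_total=n_total,
        n_conclusive=n_conclusive,
        coverage=coverage,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bal,
    )


def potency_rates(predicted: Sequence[str], truth: Sequence[str]) -> MetricsReport:
    """Correct / under / over-prediction rates under the ordering NC < 1B < 1A.

    Rates are fractions of *conclusive* predictions (they sum to 100 %);
    inconclusive predictions count only against coverage.
    """
    if len(predicted) != len(truth):
        raise ValidationError("predicted and truth lengths differ")
    for t in truth:
        if t not in POTENCY_ORDER:
            raise ValidationError(f"truth potency {t!r} not in {tuple(POTENCY_ORDER)}")
    n_total = len(predicted)
    correct = under = over = 0
    for p, t in zip(predicted, truth):
        if p == "inconclusive":
            continue
        if p not in POTENCY_ORDER:
            raise ValidationError(f"predicted potency {p!r} unrecognized")
        if POTENCY_ORDER[p] == POTENCY_ORDER[t]:
            correct += 1
        elif POTENCY_ORDER[p] < POTENCY_ORDER[t]:
            under += 1
        else:
            over += 1
    n_conclusive = correct + under + over
    coverage = 100.0 * n_conclusive / n_total if n_total else 0.0
    if n_conclusive == 0:
        return MetricsReport(n_total=n_total, n_conclusive=0, coverage=coverage)
    return MetricsReport(
        n_total=n_total,
        n_conclusive=n_conclusive,
        coverage=coverage,
        potency_correct=100.0 * correct / n_conclusive,
        potency_under=100.0 * under / n_conclusive,
        potency_over=100.0 * over / n_conclusive,
    )


def report_to_dict(report: MetricsReport, digits: Optional[int] = None) -> dict:
    """Flatten a MetricsReport to a JSON-friendly dict (optionally rounded)."""
    out = {
        "n_total": report.n_total,
        "n_conclusive": report.n_conclusive,
        "coverage_pct": report.coverage,
    }
    if report.counts is not None:
        out.update(tp=report.counts.tp, tn=report.counts.tn,
                   fp=report.counts.fp, fn=report.counts.fn)
    for name in ("sensitivity", "specificity", "accuracy", "balanced_accuracy",
                 "potency_correct", "potency_under", "potency_over"):
        value = getattr(report, name)
        if value is not None:
            out[f"{name}_pct"] = value
    if digits is not None:
        out = {k: (round(v, digits) if isinstance(v, float) else v) for k, v in out.items()}
    return out
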