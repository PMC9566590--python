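"""Performance measures for hazard and potency predictions.

Definitions (positive class = sensitizer):

    accuracy          = (TP + TN) / (TP + TN + FP + FN)
    sensitivity       = TP / (TP + FN)
    specificity       = TN / (TN + FP)
    balanced accuracy = (sensitivity + specificity) / 2
    coverage          = conclusive predictions / all predictions

Inconclusive predictions are excluded from every numerator and denominator
above except coverage. An undefined ratio (empty denominator) is reported
as None — never silently as zero. Display rounding is half-up to integer
percent; raw reals are kept in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .records import Hazard, Potency

__all__ = [
    "BinaryConfusion", "BinaryMetrics", "PotencyBreakdown",
    "tabulate_binary", "binary_metrics", "balanced_accuracy",
    "potency_breakdown", "benchmark_report", "round_half_up_pct", "prevalence",
]


def round_half_up_pct(fraction: Optional[float]) -> Optional[int]:
    """Round a fraction in [0, 1] to integer percent, ties away from zero."""
    if fraction is None:
        return None
    return int(math.floor(fraction * 100.0 + 0.5))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def prevalence(ref: Sequence[Hazard | str]) -> float:
    """Fraction of reference labels that are sensitizers."""
    labels = [_coerce_hazard(r, i) for i, r in enumerate(ref)]
    if not labels:
        raise ValidationError("empty reference list", field="ref")
    return sum(1 for r in labels if r is Hazard.SENSITIZER) / len(labels)


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    tn: int
    fp: int
    fn: int
    n_total: int

    @property
    def n_conclusive(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValidationError("confusion counts must be non-negative",
                                  field="confusion")
        if self.n_conclusive > self.n_total:
            raise ValidationError("conclusive count exceeds total",
                                  field="n_total")


@dataclass(frozen=True)
class BinaryMetrics:
    """Computed measures; a field is None when its ratio is undefined."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: Optional[float]
    coverage: float

    def as_dict(self, percent: bool = False) -> dict[str, Optional[float | int]]:
        d = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
             "specificity": self.specificity,
             "balanced_accuracy": self.balanced_accuracy,
             "coverage": self.coverage}
        if percent:
            return {k: round_half_up_pct(v) for k, v in d.items()}
        return d


@dataclass(frozen=True)
class PotencyBreakdown:
    """Per-subcategory and overall correct-classification rates."""

    rate_1a: Optional[float]
    rate_1b: Optional[float]
    rate_nc: Optional[float]
    overall: Optional[float]
    coverage: float

    def as_dict(self, percent: bool = False) -> dict[str, Optional[float | int]]:
        d = {"1A": self.rate_1a, "1B": self.rate_1b, "NC": self.rate_nc,
             "overall": self.overall, "coverage": self.coverage}
        if percent:
            return {k: round_half_up_pct(v) for k, v in d.items()}
        return d


def _coerce_hazard(label: Hazard | str, idx: int) -> Hazard:
    if isinstance(label, Hazard):
        return label
    try:
        return Hazard(label)
    except ValueError:
        raise ValidationError(f"unknown hazard label {label!r}",
                              record_id=str(idx)) from None


def _coerce_potency(label: Potency | str, idx: int) -> Potency:
    if isinstance(label, Potency):
        return label
    try:
        return Potency(label)
    except ValueError:
        raise ValidationError(f"unknown potency label {label!r}",
                              record_id=str(idx)) from None


def tabulate_binary(pred: Sequence[Hazard | str],
                    ref: Sequence[Hazard | str]) -> BinaryConfusion:
    """Count TP/TN/FP/FN over conclusive predictions.

    Inconclusive predictions are excluded from the counts but still appear
    in ``n_total`` (and hence reduce coverage). References must be
    conclusive.
    """
    if len(pred) != len(ref):
        raise ValidationError(
            f"length mismatch: {len(pred)} predictions vs {len(ref)} references",
            field="pred/ref")
    tp = tn = fp = fn = 0
    for i, (p_raw, r_raw) in enumerate(zip(pred, ref)):
        p = _coerce_hazard(p_raw, i)
        r = _coerce_hazard(r_raw, i)
        if r is Hazard.INCONCLUSIVE:
            raise ValidationError("reference label may not be inconclusive",
                                  record_id=str(i), field="ref")
        if p is Hazard.INCONCLUSIVE:
            continue
        if r is Hazard.SENSITIZER:
            if p is Hazard.SENSITIZER:
                tp += 1
            else:
                fn += 1
        else:
            if p is Hazard.NON_SENSITIZER:
                tn += 1
            else:
                fp += 1
    return BinaryConfusion(tp=tp, tn=tn, fp=fp, fn=fn, n_total=len(pred))


def binary_metrics(c: BinaryConfusion) -> BinaryMetrics:
    """Accuracy, sensitivity, specificity, balanced accuracy and coverage
    from a confusion table. Requires at least one conclusive prediction."""
    if c.n_conclusive == 0:
        raise ValidationError("no conclusive predictions to evaluate",
                              field="confusion")
    acc = (c.tp + c.tn) / c.n_conclusive
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    ba = balanced_accuracy(sens, spec) if sens is not None and spec is not None \
        else None
    cov = c.n_conclusive / c.n_total if c.n_total > 0 else 0.0
    return BinaryMetrics(accuracy=acc, sensitivity=sens, specificity=spec,
                         balanced_accuracy=ba, coverage=cov)


def potency_breakdown(pred: Sequence[Potency | str],
                      ref: Sequence[Potency | str]) -> PotencyBreakdown:
    """Correct-classification rate per reference subcategory and overall.

    Each per-category denominator is the number of conclusive predictions
    among records whose reference is that category; an empty category
    yields a None rate. Coverage counts conclusive predictions over all
    records.
    """
    if len(pred) != len(ref):
        raise ValidationError(
            f"length mismatch: {len(pred)} predictions vs {len(ref)} references",
            field="pred/ref")
    correct = {Potency.CAT_1A: 0, Potency.CAT_1B: 0, Potency.NC: 0}
    conclusive = {Potency.CAT_1A: 0, Potency.CAT_1B: 0, Potency.NC: 0}
    for i, (p_raw, r_raw) in enumerate(zip(pred, ref)):
        p = _coerce_potency(p_raw, i)
        r = _coerce_potency(r_raw, i)
        if r is Potency.INCONCLUSIVE:
            raise ValidationError("reference potency may not be inconclusive",
                                  record_id=str(i), field="ref")
        if p is Potency.INCONCLUSIVE:
            continue
        conclusive[r] += 1
        if p is r:
            correct[r] += 1

    def _rate(cat: Potency) -> Optional[float]:
        return correct[cat] / conclusive[cat] if conclusive[cat] > 0 else None

    n_conc = sum(conclusive.values())
    overall = sum(correct.values()) / n_conc if n_conc > 0 else None
    cov = n_conc / len(pred) if pred else 0.0
    return PotencyBreakdown(rate_1a=_rate(Potency.CAT_1A),
                            rate_1b=_rate(Potency.CAT_1B),
                            rate_nc=_rate(Potency.NC),
                            overall=overall, coverage=cov)


# -- report assembly -------------------------------------------------------

def benchmark_report(hazard_results: Mapping[str, tuple[Sequence, Sequence]],
                     potency_results: Mapping[str, tuple[Sequence, Sequence]]
                     | None = None) -> dict:
    """Assemble a multi-method evaluation report.

    Parameters
    ----------
    hazard_results : mapping of method name -> (predicted hazard calls,
        reference hazard labels).
    potency_results : optional mapping of method name -> (predicted potency
        calls, reference potency labels).

    Returns a dict with ``raw`` (full-precision metrics), ``percent``
    (half-up integer percents) and ``text`` (aligned plain-text tables).
    """
    raw: dict[str, dict] = {"hazard": {}, "potency": {}}
    pct: dict[str, dict] = {"hazard": {}, "potency": {}}
    for method, (pred, ref) in hazard_results.items():
        m = binary_metrics(tabulate_binary(pred, ref))
        raw["hazard"][method] = m.as_dict()
        pct["hazard"][method] = m.as_dict(percent=True)
    for method, (pred, ref) in (potency_results or {}).items():
        b = potency_breakdown(pred, ref)
        raw["potency"][method] = b.as_dict()
        pct["potency"][method] = b.as_dict(percent=True)

    lines: list[str] = []
    if pct["hazard"]:
        df = pd.DataFrame(pct["hazard"]).T
        df = df[["balanced_accuracy", "sensitivity", "specificity", "coverage"]]
        df.columns = ["Balanced Accuracy (%)", "Sensitivity (%)",
                      "Specificity (%)", "Coverage (%)"]
        lines += ["Hazard identification", df.to_string(), ""]
    if pct["potency"]:
        df = pd.DataFrame(pct["potency"]).T
        df = df[["coverage", "overall", "1A", "1B", "NC"]]
        df.columns = ["Coverage (%)", "Overall (%)", "1A (%)", "1B (%)",
                      "NC (%)"]
        lines += ["Potency classification", df.to_string(), ""]
    return {"raw": raw, "percent": pct, "text": "\n".join(lines)}
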