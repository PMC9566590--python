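"""Domain records: assay results, in silico calls, and categorical outcomes."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError

__all__ = [
    "Hazard", "Potency", "DPRAResult", "HCLATResult", "InSilicoCall",
    "ChemicalRecord", "ITSScore",
]

DEPLETION_MIN = -20.0   # assay noise tolerance; beyond this looks like a unit error
DEPLETION_MAX = 100.0


class Hazard(str, enum.Enum):
    """Binary hazard outcome, with an explicit inconclusive level."""

    SENSITIZER = "sensitizer"
    NON_SENSITIZER = "non-sensitizer"
    INCONCLUSIVE = "inconclusive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Potency(str, enum.Enum):
    """GHS potency subcategory, with an explicit inconclusive level."""

    CAT_1A = "1A"
    CAT_1B = "1B"
    NC = "NC"
    INCONCLUSIVE = "inconclusive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DPRAResult:
    """Peptide-depletion readout: percent depletion of cys and lys peptides.

    When the lysine peptide co-elutes (``lys_coelution``) its depletion value
    is unusable and the cysteine-only scoring table applies.
    """

    cys_depletion: float
    lys_depletion: Optional[float] = None
    lys_coelution: bool = False

    def validate(self, record_id: str | None = None) -> None:
        if not DEPLETION_MIN <= self.cys_depletion <= DEPLETION_MAX:
            raise ValidationError(
                f"cys depletion {self.cys_depletion} outside "
                f"[{DEPLETION_MIN}, {DEPLETION_MAX}]",
                record_id=record_id, field="dpra_cys")
        if not self.lys_coelution and self.lys_depletion is not None:
            if not DEPLETION_MIN <= self.lys_depletion <= DEPLETION_MAX:
                raise ValidationError(
                    f"lys depletion {self.lys_depletion} outside "
                    f"[{DEPLETION_MIN}, {DEPLETION_MAX}]",
                    record_id=record_id, field="dpra_lys")


@dataclass(frozen=True)
class HCLATResult:
    """Dendritic-cell activation readout.

    ``mit`` is the minimum induction threshold in ug/mL; it is required (and
    positive) exactly when the outcome is positive.
    """

    outcome: str  # "positive" | "negative"
    mit: Optional[float] = None

    def validate(self, record_id: str | None = None) -> None:
        if self.outcome not in ("positive", "negative"):
            raise ValidationError(
                f"unknown h-CLAT outcome {self.outcome!r}",
                record_id=record_id, field="hclat_outcome")
        if self.outcome == "positive":
            if self.mit is None or not self.mit > 0:
                raise ValidationError(
                    "positive h-CLAT outcome requires mit > 0",
                    record_id=record_id, field="hclat_mit")
        elif self.mit is not None:
            raise ValidationError(
                "negative h-CLAT outcome must not carry an mit",
                record_id=record_id, field="hclat_mit")


@dataclass(frozen=True)
class InSilicoCall:
    """A structure-based prediction: score in [0, 1] plus a domain flag."""

    score: float
    in_domain: bool = True
    source: str = "insilico"

    def validate(self, record_id: str | None = None) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"in silico score {self.score} outside [0, 1]",
                record_id=record_id, field="insilico_score")


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical's bundle of assay, in silico, and reference data."""

    id: str
    smiles: Optional[str] = None
    dpra: Optional[DPRAResult] = None
    hclat: Optional[HCLATResult] = None
    insilico: Optional[InSilicoCall] = None
    ref_hazard: Optional[Hazard] = None
    ref_potency: Optional[Potency] = None

    def validate(self) -> None:
        if self.dpra is not None:
            self.dpra.validate(self.id)
        if self.hclat is not None:
            self.hclat.validate(self.id)
        if self.insilico is not None:
            self.insilico.validate(self.id)
        if self.ref_hazard is not None and self.ref_hazard is Hazard.INCONCLUSIVE:
            raise ValidationError("reference hazard cannot be inconclusive",
                                  record_id=self.id, field="ref_hazard")
        if self.ref_potency is not None and self.ref_hazard is not None:
            sens = self.ref_potency in (Potency.CAT_1A, Potency.CAT_1B)
            if sens and self.ref_hazard is not Hazard.SENSITIZER:
                raise ValidationError(
                    "potency 1A/1B requires a sensitizer reference hazard",
                    record_id=self.id, field="ref_potency")
            if self.ref_potency is Potency.NC and \
                    self.ref_hazard is not Hazard.NON_SENSITIZER:
                raise ValidationError(
                    "potency NC requires a non-sensitizer reference hazard",
                    record_id=self.id, field="ref_potency")


@dataclass(frozen=True)
class ITSScore:
    """Component points and their sum; the total is None when any
    component is missing (the inconclusive case)."""

    dpra_points: Optional[int]
    hclat_points: Optional[int]
    insilico_points: Optional[int]

    @property
    def total(self) -> Optional[int]:
        parts = (self.dpra_points, self.hclat_points, self.insilico_points)
        if any(p is None for p in parts):
            return None
        return sum(parts)  # type: ignore[arg-type]

    @property
    def is_conclusive(self) -> bool:
        return self.total is not None
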