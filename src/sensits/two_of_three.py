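"""Two-out-of-three consensus hazard call over the three key-event assays.

Each of the peptide-binding (DPRA), keratinocyte-activation (KeratinoSens)
and dendritic-cell-activation (h-CLAT) assays delivers a positive, negative
or missing outcome; two concordant conclusive outcomes decide the hazard
call. Per-assay positivity is consumed as input, never derived from raw
values here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import ValidationError
from .records import Hazard

__all__ = ["ASSAYS", "AssayCall", "call_2o3"]

ASSAYS = ("DPRA", "KeratinoSens", "hCLAT")
_OUTCOMES = ("positive", "negative", "missing")


@dataclass(frozen=True)
class AssayCall:
    """One assay's binary outcome for one chemical."""

    assay: str      # one of ASSAYS
    outcome: str    # "positive" | "negative" | "missing"

    def validate(self, record_id: str | None = None) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay label {self.assay!r} "
                                  f"(expected one of {ASSAYS})",
                                  record_id=record_id, field="assay")
        if self.outcome not in _OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r} "
                                  f"(expected one of {_OUTCOMES})",
                                  record_id=record_id, field="outcome")


def call_2o3(calls: Iterable[AssayCall] | Mapping[str, str],
             require_all_three: bool = False,
             record_id: Optional[str] = None) -> Hazard:
    """Consensus hazard call from exactly one outcome per assay.

    Two concordant conclusive outcomes decide (>=2 positive -> sensitizer,
    >=2 negative -> non-sensitizer); anything less concordant is
    inconclusive. With ``require_all_three`` a missing outcome forces
    inconclusive even when the other two agree.
    """
    if isinstance(calls, Mapping):
        calls = [AssayCall(a, o) for a, o in calls.items()]
    else:
        calls = list(calls)
    seen: dict[str, str] = {}
    for c in calls:
        c.validate(record_id)
        if c.assay in seen:
            raise ValidationError(f"duplicate call for assay {c.assay!r}",
                                  record_id=record_id, field="assay")
        seen[c.assay] = c.outcome
    if set(seen) != set(ASSAYS):
        missing = sorted(set(ASSAYS) - set(seen))
        raise ValidationError(f"missing call(s) for assay(s): {missing}",
                              record_id=record_id, field="assay")

    outcomes = list(seen.values())
    if require_all_three and "missing" in outcomes:
        return Hazard.INCONCLUSIVE
    n_pos = outcomes.count("positive")
    n_neg = outcomes.count("negative")
    if n_pos >= 2:
        return Hazard.SENSITIZER
    if n_neg >= 2:
        return Hazard.NON_SENSITIZER
    return Hazard.INCONCLUSIVE
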