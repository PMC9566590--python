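"""Mixture hazard classification from per-ingredient calls and concentrations.

A mixture is a sensitizer if any ingredient above the 0.1% (w/w, strict)
concentration threshold is called a sensitizer. If no above-threshold
ingredient is a sensitizer but one of them is inconclusive, the mixture is
inconclusive: a conclusive non-sensitizer claim must not rest on an
unresolved ingredient. Ingredients at or below the threshold never affect
the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import MissingCallError, ValidationError
from .records import Hazard

__all__ = ["CONCENTRATION_THRESHOLD_PCT", "MixtureComponent", "MixtureRecord",
           "classify_mixture"]

CONCENTRATION_THRESHOLD_PCT = 0.1


@dataclass(frozen=True)
class MixtureComponent:
    """One ingredient of a mixture with its concentration in percent w/w."""

    ingredient_id: str
    concentration: float  # percent w/w, in (0, 100]

    def validate(self, mixture_id: str | None = None) -> None:
        if not 0.0 < self.concentration <= 100.0:
            raise ValidationError(
                f"concentration {self.concentration} of ingredient "
                f"{self.ingredient_id!r} outside (0, 100]",
                record_id=mixture_id, field="concentration")


@dataclass(frozen=True)
class MixtureRecord:
    """A mixture: unique ingredient components summing to at most 100%."""

    mixture_id: str
    components: tuple[MixtureComponent, ...] = field(default_factory=tuple)
    ref_hazard: Optional[Hazard] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    def validate(self) -> None:
        ids = [c.ingredient_id for c in self.components]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ingredient id(s): {dupes}",
                                  record_id=self.mixture_id, field="components")
        for c in self.components:
            c.validate(self.mixture_id)
        total = sum(c.concentration for c in self.components)
        if total > 100.0 + 1e-9:
            raise ValidationError(
                f"component concentrations sum to {total:g}% > 100%",
                record_id=self.mixture_id, field="components")


def classify_mixture(mix: MixtureRecord,
                     ingredient_calls: Mapping[str, Hazard]) -> Hazard:
    """Classify a mixture from per-ingredient hazard calls.

    Raises :class:`MissingCallError` listing the ingredient ids that lack
    a hazard call.
    """
    mix.validate()
    missing = [c.ingredient_id for c in mix.components
               if c.ingredient_id not in ingredient_calls]
    if missing:
        raise MissingCallError(missing, mixture_id=mix.mixture_id)

    above = [c for c in mix.components
             if c.concentration > CONCENTRATION_THRESHOLD_PCT]
    calls = [ingredient_calls[c.ingredient_id] for c in above]
    if any(c is Hazard.SENSITIZER for c in calls):
        return Hazard.SENSITIZER
    if any(c is Hazard.INCONCLUSIVE for c in calls):
        return Hazard.INCONCLUSIVE
    return Hazard.NON_SENSITIZER
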