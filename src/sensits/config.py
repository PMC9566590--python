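"""Scoring configuration: bin edges, cutoffs, and decision ranges.

The default bin edges for the DPRA and h-CLAT point tables are taken from
OECD Guideline No. 497 (the integrated-testing-strategy defined approach);
they are deliberately user-overridable so the engine survives guideline
revisions. All comparisons follow the guideline convention: DPRA lower bin
edges are inclusive upward (value >= edge earns the higher score), h-CLAT
edges are inclusive toward the higher score (MIT <= edge earns it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError

__all__ = ["ScoringConfig", "DEFAULT_CONFIG"]


def _as_tuple(value: Any, n: int, name: str, cast=float) -> tuple:
    try:
        t = tuple(cast(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"expected a sequence of {n} numbers, got {value!r}",
                              field=name) from exc
    if len(t) != n:
        raise ValidationError(f"expected {n} entries, got {len(t)}", field=name)
    return t


@dataclass(frozen=True)
class ScoringConfig:
    """All thresholds used by the scoring engine.

    Attributes
    ----------
    dpra_mean_bins : tuple of 3 ascending percent edges for the mean
        cys/lys depletion table (``mean >= edge`` earns the next point).
    dpra_cysonly_bins : tuple of 3 ascending percent edges for the
        cysteine-only table used when lysine co-elutes.
    hclat_mit_bins : tuple of 3 ascending MIT edges in ug/mL
        (``mit <= edge`` earns the higher point).
    insilico_cutoff : strict cutoff on the in silico score; a score
        strictly greater than the cutoff earns 1 point.
    hazard_sensitizer_range : inclusive total-score interval called
        sensitizer; anything below is a non-sensitizer.
    potency_1a_range, potency_1b_range : inclusive total-score intervals
        for GHS subcategories 1A and 1B; the remainder is NC.
    """

    dpra_mean_bins: tuple[float, float, float] = (6.38, 22.62, 42.47)
    dpra_cysonly_bins: tuple[float, float, float] = (13.89, 23.09, 98.24)
    hclat_mit_bins: tuple[float, float, float] = (10.0, 150.0, 5000.0)
    insilico_cutoff: float = 0.5
    hazard_sensitizer_range: tuple[int, int] = (2, 7)
    potency_1a_range: tuple[int, int] = (6, 7)
    potency_1b_range: tuple[int, int] = (2, 5)

    def __post_init__(self) -> None:
        for name in ("dpra_mean_bins", "dpra_cysonly_bins", "hclat_mit_bins"):
            edges = _as_tuple(getattr(self, name), 3, name)
            object.__setattr__(self, name, edges)
            if not (edges[0] < edges[1] < edges[2]):
                raise ValidationError("bin edges must be strictly ascending",
                                      field=name)
        for name in ("hazard_sensitizer_range", "potency_1a_range",
                     "potency_1b_range"):
            lo, hi = _as_tuple(getattr(self, name), 2, name, cast=int)
            object.__setattr__(self, name, (lo, hi))
            if not (0 <= lo <= hi <= 7):
                raise ValidationError("range must satisfy 0 <= lo <= hi <= 7",
                                      field=name)
        a_lo, a_hi = self.potency_1a_range
        b_lo, b_hi = self.potency_1b_range
        if max(a_lo, b_lo) <= min(a_hi, b_hi):
            raise ValidationError("potency 1A and 1B ranges must be disjoint",
                                  field="potency_1a_range")
        if not 0.0 <= float(self.insilico_cutoff) <= 1.0:
            raise ValidationError("cutoff must lie in [0, 1]",
                                  field="insilico_cutoff")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {f.name: list(v) if isinstance(v := getattr(self, f.name), tuple)
                else v for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScoringConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}",
                                  field="config")
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True,
                              default_flow_style=None)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScoringConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a mapping",
                                  field="config")
        return cls.from_dict(data)

    def replace(self, **kwargs: Any) -> "ScoringConfig":
        d = self.to_dict()
        d.update(kwargs)
        return self.from_dict(d)


DEFAULT_CONFIG = ScoringConfig()
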