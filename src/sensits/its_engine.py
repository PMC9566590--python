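"""Point scoring and hazard/potency calls for the score-summation strategy.

The strategy integrates three information sources — peptide reactivity
(DPRA), dendritic-cell activation (h-CLAT), and an in silico predictor —
into an additive score:

* DPRA contributes 0-3 points, binned on the mean percent depletion of the
  cysteine and lysine peptides (cysteine-only table when lysine co-elutes);
* h-CLAT contributes 0-3 points, with a smaller minimum induction threshold
  (MIT) earning more points and a negative outcome earning 0;
* the in silico predictor contributes 1 point when its score exceeds the
  cutoff (strictly) and it is inside its applicability domain, else 0.

The total (0-7) is mapped onto hazard (>= 2 is a sensitizer) and GHS
potency (6-7 -> 1A, 2-5 -> 1B, rest NC). Any missing component — including
an out-of-domain in silico prediction — makes the whole call inconclusive.
"""

from __future__ import annotations

from typing import Optional

from .config import DEFAULT_CONFIG, ScoringConfig
from .records import (ChemicalRecord, DPRAResult, HCLATResult, Hazard,
                      InSilicoCall, ITSScore, Potency)

__all__ = [
    "score_dpra", "score_hclat", "score_insilico", "compute_its_score",
    "call_hazard", "call_potency", "assess_record",
]


def _bin_ascending(value: float, edges: tuple[float, float, float]) -> int:
    """Points = number of edges at or below ``value`` (lower-edge inclusive)."""
    return sum(1 for e in edges if value >= e)


def _bin_descending(value: float, edges: tuple[float, float, float]) -> int:
    """Points = 3 minus the number of edges strictly below ``value``;
    edges are inclusive toward the higher score (value <= edge keeps it)."""
    return 3 - sum(1 for e in edges if value > e)


def score_dpra(dpra: Optional[DPRAResult], cfg: ScoringConfig = DEFAULT_CONFIG,
               record_id: str | None = None) -> Optional[int]:
    """Score the peptide-reactivity result on the 0-3 point table.

    Returns None for a missing input. Uses the mean of cys and lys percent
    depletion against ``cfg.dpra_mean_bins``; falls back to the
    cysteine-only table when the lysine peptide co-elutes (or lys depletion
    is unavailable).
    """
    if dpra is None:
        return None
    dpra.validate(record_id)
    if dpra.lys_coelution or dpra.lys_depletion is None:
        return _bin_ascending(dpra.cys_depletion, cfg.dpra_cysonly_bins)
    mean = (dpra.cys_depletion + dpra.lys_depletion) / 2.0
    return _bin_ascending(mean, cfg.dpra_mean_bins)


def score_hclat(hclat: Optional[HCLATResult], cfg: ScoringConfig = DEFAULT_CONFIG,
                record_id: str | None = None) -> Optional[int]:
    """Score the h-CLAT result: negative -> 0; positive binned by MIT with
    lower MIT earning more points (edges inclusive toward the higher score).
    Returns None for a missing input."""
    if hclat is None:
        return None
    hclat.validate(record_id)
    if hclat.outcome == "negative":
        return 0
    return _bin_descending(hclat.mit, cfg.hclat_mit_bins)  # type: ignore[arg-type]


def score_insilico(call: Optional[InSilicoCall],
                   cfg: ScoringConfig = DEFAULT_CONFIG,
                   record_id: str | None = None) -> Optional[int]:
    """Score the in silico prediction: 1 point iff the score is strictly
    greater than the cutoff. Out-of-domain predictions are discarded
    (None), as is a missing call."""
    if call is None:
        return None
    call.validate(record_id)
    if not call.in_domain:
        return None
    return 1 if call.score > cfg.insilico_cutoff else 0


def compute_its_score(rec: ChemicalRecord,
                      cfg: ScoringConfig = DEFAULT_CONFIG) -> ITSScore:
    """Score all three components of a record; the total is None
    (inconclusive) unless all three are present."""
    rec.validate()
    return ITSScore(
        dpra_points=score_dpra(rec.dpra, cfg, rec.id),
        hclat_points=score_hclat(rec.hclat, cfg, rec.id),
        insilico_points=score_insilico(rec.insilico, cfg, rec.id),
    )


def call_hazard(score: ITSScore, cfg: ScoringConfig = DEFAULT_CONFIG) -> Hazard:
    """Map a total score to a hazard call: totals inside
    ``cfg.hazard_sensitizer_range`` are sensitizers, totals below it are
    non-sensitizers, an undefined total is inconclusive."""
    total = score.total
    if total is None:
        return Hazard.INCONCLUSIVE
    lo, hi = cfg.hazard_sensitizer_range
    return Hazard.SENSITIZER if lo <= total <= hi else Hazard.NON_SENSITIZER


def call_potency(score: ITSScore, cfg: ScoringConfig = DEFAULT_CONFIG) -> Potency:
    """Map a total score to a GHS potency subcategory (1A / 1B / NC);
    an undefined total is inconclusive."""
    total = score.total
    if total is None:
        return Potency.INCONCLUSIVE
    a_lo, a_hi = cfg.potency_1a_range
    if a_lo <= total <= a_hi:
        return Potency.CAT_1A
    b_lo, b_hi = cfg.potency_1b_range
    if b_lo <= total <= b_hi:
        return Potency.CAT_1B
    return Potency.NC


def assess_record(rec: ChemicalRecord, cfg: ScoringConfig = DEFAULT_CONFIG
                  ) -> tuple[ITSScore, Hazard, Potency]:
    """End-to-end convenience: score a record and derive both calls."""
    score = compute_its_score(rec, cfg)
    return score, call_hazard(score, cfg), call_potency(score, cfg)
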