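"""Deterministic synthetic panels and mixtures for testing every stage.

Panels are generated label-first: each record gets a planted reference
hazard/potency, then assay values are drawn uniformly *inside* the scoring
bin intervals that realize a label-concordant total. This guarantees that
(a) with no missingness the engine recovers every planted label exactly,
and (b) every scoring branch is exercised once the panel is large enough
(the first 32 records enumerate all component-point triples).

A single integer seed drives one ``numpy.random.Generator``; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, ScoringConfig
from .errors import ValidationError
from .mixtures import MixtureComponent, MixtureRecord, classify_mixture
from .records import (ChemicalRecord, DPRAResult, HCLATResult, Hazard,
                      InSilicoCall, Potency)

__all__ = ["PanelSpec", "generate_panel", "generate_assay_calls",
           "generate_mixtures", "enumerate_score_space", "ALL_TRIPLES"]

#: every (dpra, hclat, insilico) component-point combination
ALL_TRIPLES: tuple[tuple[int, int, int], ...] = tuple(
    (d, h, s) for d in range(4) for h in range(4) for s in range(2))

DEPLETION_MIN = -20.0
DEPLETION_MAX = 100.0


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic chemical panel."""

    n_chemicals: int
    prevalence: float = 0.83       # sensitizer fraction among planted labels
    missing_rate: float = 0.0      # per-component probability of a missing input
    out_of_domain_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValidationError("n_chemicals must be >= 1", field="n_chemicals")
        for name in ("prevalence", "missing_rate", "out_of_domain_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]", field=name)


# -- score-space oracle ----------------------------------------------------

def enumerate_score_space(cfg: ScoringConfig = DEFAULT_CONFIG
                          ) -> list[dict]:
    """Exhaustive table of all 32 component-point triples with the total and
    the hazard/potency categories they must map to.

    Implemented by direct arithmetic on the configured ranges — independent
    of the scoring engine — so it can serve as a golden oracle in tests.
    """
    h_lo, h_hi = cfg.hazard_sensitizer_range
    a_lo, a_hi = cfg.potency_1a_range
    b_lo, b_hi = cfg.potency_1b_range
    rows = []
    for d, h, s in ALL_TRIPLES:
        total = d + h + s
        hazard = Hazard.SENSITIZER if h_lo <= total <= h_hi \
            else Hazard.NON_SENSITIZER
        if a_lo <= total <= a_hi:
            potency = Potency.CAT_1A
        elif b_lo <= total <= b_hi:
            potency = Potency.CAT_1B
        else:
            potency = Potency.NC
        rows.append({"dpra_points": d, "hclat_points": h, "insilico_points": s,
                     "total": total, "hazard": hazard, "potency": potency})
    return rows


# -- value sampling inside bin intervals -----------------------------------

def _ascending_interval(points: int, edges: tuple[float, float, float],
                        lo: float, hi: float) -> tuple[float, float]:
    """Value interval realizing ``points`` under lower-edge-inclusive binning."""
    bounds = (lo, *edges, hi)
    return bounds[points], bounds[points + 1]


def _sample_dpra(points: int, rng: np.random.Generator,
                 cfg: ScoringConfig) -> DPRAResult:
    coelution = bool(rng.random() < 0.2)
    if coelution:
        a, b = _ascending_interval(points, cfg.dpra_cysonly_bins,
                                   DEPLETION_MIN, DEPLETION_MAX)
        return DPRAResult(cys_depletion=float(rng.uniform(a, b)),
                          lys_coelution=True)
    a, b = _ascending_interval(points, cfg.dpra_mean_bins,
                               DEPLETION_MIN, DEPLETION_MAX)
    mean = float(rng.uniform(a, b))
    # split the mean asymmetrically while keeping both values in range
    spread = min(mean - DEPLETION_MIN, DEPLETION_MAX - mean)
    delta = float(rng.uniform(0, spread))
    return DPRAResult(cys_depletion=mean + delta, lys_depletion=mean - delta)


def _sample_hclat(points: int, rng: np.random.Generator,
                  cfg: ScoringConfig) -> HCLATResult:
    if points == 0:
        return HCLATResult(outcome="negative")
    e1, e2, e3 = cfg.hclat_mit_bins
    # MIT <= e1 -> 3, (e1, e2] -> 2, (e2, e3] -> 1
    lo, hi = {3: (min(0.5, e1 / 2), e1), 2: (e1, e2), 1: (e2, e3)}[points]
    mit = float(rng.uniform(lo, hi))
    if mit <= lo:  # guard the open lower edge for points < 3
        mit = (lo + hi) / 2
    return HCLATResult(outcome="positive", mit=mit)


def _sample_insilico(points: int, rng: np.random.Generator,
                     cfg: ScoringConfig) -> InSilicoCall:
    cut = cfg.insilico_cutoff
    if points == 1:
        score = float(rng.uniform(min(cut + 1e-6, 1.0), 1.0))
        score = max(score, min(cut + 1e-6, 1.0))
    else:
        score = float(rng.uniform(0.0, cut))
    return InSilicoCall(score=score, in_domain=True)


# -- panel generation ------------------------------------------------------

def _triples_for_label(sensitizer: bool,
                       cfg: ScoringConfig) -> list[tuple[int, int, int]]:
    lo, hi = cfg.hazard_sensitizer_range
    keep = []
    for t in ALL_TRIPLES:
        total = sum(t)
        is_sens = lo <= total <= hi
        if is_sens == sensitizer:
            keep.append(t)
    return keep


def generate_panel(spec: PanelSpec,
                   cfg: ScoringConfig = DEFAULT_CONFIG) -> list[ChemicalRecord]:
    """Generate a reproducible panel of chemical records.

    The first ``min(n, 32)`` records enumerate all component-point triples
    (their planted labels follow from the triple totals); further records
    draw a label from the prevalence and then a label-concordant triple.
    Missingness and out-of-domain flags are then applied per component.
    """
    rng = np.random.default_rng(spec.seed)
    h_lo, h_hi = cfg.hazard_sensitizer_range
    a_lo, a_hi = cfg.potency_1a_range
    b_lo, b_hi = cfg.potency_1b_range

    plan: list[tuple[int, int, int]] = []
    seed_triples = list(ALL_TRIPLES)
    rng.shuffle(seed_triples)
    for i in range(spec.n_chemicals):
        if i < len(seed_triples):
            plan.append(seed_triples[i])
        else:
            sens = bool(rng.random() < spec.prevalence)
            pool = _triples_for_label(sens, cfg)
            plan.append(pool[int(rng.integers(len(pool)))])

    records: list[ChemicalRecord] = []
    for i, (d, h, s) in enumerate(plan):
        total = d + h + s
        ref_h = Hazard.SENSITIZER if h_lo <= total <= h_hi \
            else Hazard.NON_SENSITIZER
        if a_lo <= total <= a_hi:
            ref_p = Potency.CAT_1A
        elif b_lo <= total <= b_hi:
            ref_p = Potency.CAT_1B
        else:
            ref_p = Potency.NC

        dpra = _sample_dpra(d, rng, cfg)
        hclat = _sample_hclat(h, rng, cfg)
        insil = _sample_insilico(s, rng, cfg)

        if rng.random() < spec.missing_rate:
            dpra = None
        if rng.random() < spec.missing_rate:
            hclat = None
        if rng.random() < spec.missing_rate:
            insil = None
        elif insil is not None and rng.random() < spec.out_of_domain_rate:
            insil = InSilicoCall(score=insil.score, in_domain=False,
                                 source=insil.source)

        records.append(ChemicalRecord(
            id=f"CHEM{i + 1:04d}",
            smiles="C" * (1 + i % 6),
            dpra=dpra, hclat=hclat, insilico=insil,
            ref_hazard=ref_h, ref_potency=ref_p))
    return records


def generate_assay_calls(panel: list[ChemicalRecord], missing_rate: float = 0.0,
                         seed: int = 0) -> dict[str, dict[str, str]]:
    """Per-assay binary outcomes for the two-out-of-three route, concordant
    with each record's planted reference hazard, with optional missingness."""
    rng = np.random.default_rng(seed)
    calls: dict[str, dict[str, str]] = {}
    for rec in panel:
        base = "positive" if rec.ref_hazard is Hazard.SENSITIZER else "negative"
        calls[rec.id] = {
            assay: ("missing" if rng.random() < missing_rate else base)
            for assay in ("DPRA", "KeratinoSens", "hCLAT")}
    return calls


def generate_mixtures(panel: list[ChemicalRecord], n_mixtures: int,
                      seed: int = 0) -> list[MixtureRecord]:
    """Draw mixtures of 1-5 panel ingredients with concentrations summing to
    at most 100%, planting reference hazards via the concentration-threshold
    rule on the ingredients' reference labels. Every third mixture carries
    one component at exactly the 0.1% threshold to pin the boundary."""
    if not panel:
        raise ValidationError("panel must be non-empty", field="panel")
    rng = np.random.default_rng(seed)
    by_id = {rec.id: rec for rec in panel}
    mixtures: list[MixtureRecord] = []
    for m in range(n_mixtures):
        k = int(rng.integers(1, min(5, len(panel)) + 1))
        ids = [str(x) for x in
               rng.choice([r.id for r in panel], size=k, replace=False)]
        weights = rng.dirichlet(np.ones(k))
        scale = float(rng.uniform(20.0, 99.0))
        concs = [max(float(w * scale), 0.01) for w in weights]
        if m % 3 == 0:
            concs[0] = 0.1  # exactly at the threshold: must never trigger
        comps = tuple(MixtureComponent(ingredient_id=i, concentration=c)
                      for i, c in zip(ids, concs))
        ref_calls = {i: by_id[i].ref_hazard for i in ids}
        mix = MixtureRecord(mixture_id=f"MIX{m + 1:03d}", components=comps)
        ref = classify_mixture(mix, ref_calls) \
            if all(v is not None for v in ref_calls.values()) else None
        mixtures.append(MixtureRecord(mixture_id=mix.mixture_id,
                                      components=comps, ref_hazard=ref))
    return mixtures
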