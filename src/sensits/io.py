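"""Tabular readers and writers for panels and mixtures.

Panels are delimited text with a header; empty cells and ``NA`` both mean
missing. The canonical columns are::

    id, smiles, dpra_cys, dpra_lys, dpra_coelution, hclat_outcome,
    hclat_mit, insilico_score, insilico_in_domain, ref_hazard, ref_potency,
    dpra_call, ks_call, hclat_call

(the last three feed the two-out-of-three route). Unknown columns are
preserved on the parsed frame and passed through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ValidationError
from .records import (ChemicalRecord, DPRAResult, HCLATResult, Hazard,
                      InSilicoCall, Potency)

__all__ = ["PanelData", "read_panel", "write_panel", "read_mixtures",
           "write_mixtures", "PANEL_COLUMNS"]

log = logging.getLogger("sensits")

PANEL_COLUMNS = ("id", "smiles", "dpra_cys", "dpra_lys", "dpra_coelution",
                 "hclat_outcome", "hclat_mit", "insilico_score",
                 "insilico_in_domain", "ref_hazard", "ref_potency",
                 "dpra_call", "ks_call", "hclat_call")

_MISSING = {"", "NA", "na", "NaN", "nan", "None"}
_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}

_HAZARD_ALIASES = {"sensitizer": Hazard.SENSITIZER, "sens": Hazard.SENSITIZER,
                   "non-sensitizer": Hazard.NON_SENSITIZER,
                   "non": Hazard.NON_SENSITIZER,
                   "nonsensitizer": Hazard.NON_SENSITIZER}
_POTENCY_ALIASES = {"1a": Potency.CAT_1A, "1b": Potency.CAT_1B,
                    "nc": Potency.NC}
_CALL_ALIASES = {"pos": "positive", "positive": "positive",
                 "neg": "negative", "negative": "negative"}


@dataclass
class PanelData:
    """A parsed panel: typed records, per-assay 2o3 calls, the raw frame,
    and a row-level report of lenient-mode skips."""

    records: list[ChemicalRecord]
    assay_calls: dict[str, dict[str, str]]
    frame: pd.DataFrame
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def by_id(self) -> dict[str, ChemicalRecord]:
        return {r.id: r for r in self.records}


def _cell(row: pd.Series, col: str) -> Optional[str]:
    if col not in row.index:
        return None
    v = str(row[col]).strip()
    return None if v in _MISSING else v


def _parse_float(raw: Optional[str], col: str, row_no: int) -> Optional[float]:
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"malformed number {raw!r}",
                              record_id=f"row {row_no}", field=col) from None


def _parse_bool(raw: Optional[str], col: str, row_no: int,
                default: bool) -> bool:
    if raw is None:
        return default
    low = raw.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"malformed boolean {raw!r}",
                          record_id=f"row {row_no}", field=col)


def _parse_row(row: pd.Series, row_no: int) -> tuple[ChemicalRecord,
                                                     dict[str, str]]:
    rec_id = _cell(row, "id")
    if rec_id is None:
        raise ValidationError("missing chemical id", record_id=f"row {row_no}",
                              field="id")

    dpra: Optional[DPRAResult] = None
    cys = _parse_float(_cell(row, "dpra_cys"), "dpra_cys", row_no)
    lys = _parse_float(_cell(row, "dpra_lys"), "dpra_lys", row_no)
    coel = _parse_bool(_cell(row, "dpra_coelution"), "dpra_coelution",
                       row_no, default=False)
    if cys is not None:
        dpra = DPRAResult(cys_depletion=cys, lys_depletion=lys,
                          lys_coelution=coel)
    elif lys is not None or _cell(row, "dpra_coelution") is not None:
        raise ValidationError("DPRA fields present without cys depletion",
                              record_id=rec_id, field="dpra_cys")

    hclat: Optional[HCLATResult] = None
    outcome = _cell(row, "hclat_outcome")
    mit = _parse_float(_cell(row, "hclat_mit"), "hclat_mit", row_no)
    if outcome is not None:
        low = outcome.lower()
        if low not in ("positive", "negative"):
            raise ValidationError(f"unknown h-CLAT outcome {outcome!r} "
                                  f"(row {row_no})",
                                  record_id=rec_id, field="hclat_outcome")
        hclat = HCLATResult(outcome=low, mit=mit)
    elif mit is not None:
        raise ValidationError("h-CLAT MIT present without an outcome",
                              record_id=rec_id, field="hclat_outcome")

    insilico: Optional[InSilicoCall] = None
    score = _parse_float(_cell(row, "insilico_score"), "insilico_score", row_no)
    if score is not None:
        in_dom = _parse_bool(_cell(row, "insilico_in_domain"),
                             "insilico_in_domain", row_no, default=True)
        insilico = InSilicoCall(score=score, in_domain=in_dom)

    def _categorical(col: str, aliases: dict):
        raw = _cell(row, col)
        if raw is None:
            return None
        key = raw.lower()
        if key not in aliases:
            raise ValidationError(f"unknown level {raw!r} (row {row_no})",
                                  record_id=rec_id, field=col)
        return aliases[key]

    rec = ChemicalRecord(
        id=rec_id, smiles=_cell(row, "smiles"), dpra=dpra, hclat=hclat,
        insilico=insilico,
        ref_hazard=_categorical("ref_hazard", _HAZARD_ALIASES),
        ref_potency=_categorical("ref_potency", _POTENCY_ALIASES))
    rec.validate()

    calls: dict[str, str] = {}
    for col, assay in (("dpra_call", "DPRA"), ("ks_call", "KeratinoSens"),
                       ("hclat_call", "hCLAT")):
        raw = _cell(row, col)
        if raw is None:
            calls[assay] = "missing"
            continue
        key = raw.lower()
        if key not in _CALL_ALIASES:
            raise ValidationError(f"unknown call {raw!r} (row {row_no})",
                                  record_id=rec_id, field=col)
        calls[assay] = _CALL_ALIASES[key]
    return rec, calls


def read_panel(path: str | Path, sep: str = ",",
               strict: bool = True) -> PanelData:
    """Read and validate a panel table.

    In strict mode the first invalid row aborts with a row-numbered error;
    in lenient mode invalid rows are logged, skipped, and reported in
    ``PanelData.skipped``.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "id" not in frame.columns:
        raise ValidationError(f"panel {path} lacks an 'id' column",
                              field="header")
    records: list[ChemicalRecord] = []
    assay_calls: dict[str, dict[str, str]] = {}
    skipped: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for idx, row in frame.iterrows():
        row_no = int(idx) + 2  # header is line 1
        try:
            rec, calls = _parse_row(row, row_no)
            if rec.id in seen_ids:
                raise ValidationError(f"duplicate id {rec.id!r} (row {row_no})",
                                      record_id=rec.id, field="id")
            seen_ids.add(rec.id)
        except ValidationError as exc:
            if strict:
                raise
            log.warning("skipping row %d: %s", row_no, exc)
            skipped.append((row_no, str(exc)))
            continue
        records.append(rec)
        assay_calls[rec.id] = calls
    return PanelData(records=records, assay_calls=assay_calls, frame=frame,
                     skipped=skipped)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip form
    return str(value)


def write_panel(records: list[ChemicalRecord], path: str | Path,
                assay_calls: Optional[dict[str, dict[str, str]]] = None,
                sep: str = ",") -> None:
    """Serialize records (and optional 2o3 calls) to a delimited panel."""
    rows = []
    for r in records:
        calls = (assay_calls or {}).get(r.id, {})

        def call_cell(assay: str) -> str:
            v = calls.get(assay, "missing")
            return {"positive": "pos", "negative": "neg"}.get(v, "")

        rows.append({
            "id": r.id, "smiles": _fmt(r.smiles),
            "dpra_cys": _fmt(r.dpra.cys_depletion if r.dpra else None),
            "dpra_lys": _fmt(r.dpra.lys_depletion if r.dpra else None),
            "dpra_coelution": _fmt(r.dpra.lys_coelution) if r.dpra else "",
            "hclat_outcome": _fmt(r.hclat.outcome if r.hclat else None),
            "hclat_mit": _fmt(r.hclat.mit if r.hclat else None),
            "insilico_score": _fmt(r.insilico.score if r.insilico else None),
            "insilico_in_domain": _fmt(r.insilico.in_domain)
            if r.insilico else "",
            "ref_hazard": _fmt(r.ref_hazard.value if r.ref_hazard else None),
            "ref_potency": _fmt(r.ref_potency.value if r.ref_potency else None),
            "dpra_call": call_cell("DPRA"),
            "ks_call": call_cell("KeratinoSens"),
            "hclat_call": call_cell("hCLAT"),
        })
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(
        path, sep=sep, index=False)


# -- mixtures --------------------------------------------------------------

def read_mixtures(path: str | Path, sep: str = ","):
    """Read a long-format mixture table
    (``mixture_id, ingredient_id, concentration_pct``)."""
    from .mixtures import MixtureComponent, MixtureRecord

    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    needed = {"mixture_id", "ingredient_id", "concentration_pct"}
    if not needed <= set(frame.columns):
        raise ValidationError(
            f"mixture table needs columns {sorted(needed)}", field="header")
    mixtures: dict[str, list[MixtureComponent]] = {}
    refs: dict[str, Optional[Hazard]] = {}
    for idx, row in frame.iterrows():
        row_no = int(idx) + 2
        mid = str(row["mixture_id"]).strip()
        iid = str(row["ingredient_id"]).strip()
        conc = _parse_float(str(row["concentration_pct"]).strip() or None,
                            "concentration_pct", row_no)
        if not mid or not iid or conc is None:
            raise ValidationError("incomplete mixture row",
                                  record_id=f"row {row_no}",
                                  field="mixture_id/ingredient_id")
        mixtures.setdefault(mid, []).append(
            MixtureComponent(ingredient_id=iid, concentration=conc))
        if "ref_hazard" in frame.columns:
            raw = str(row["ref_hazard"]).strip()
            if raw and raw not in _MISSING:
                refs[mid] = _HAZARD_ALIASES.get(raw.lower())
    out = [MixtureRecord(mixture_id=mid, components=tuple(comps),
                         ref_hazard=refs.get(mid))
           for mid, comps in mixtures.items()]
    for m in out:
        m.validate()
    return out


def write_mixtures(mixtures, path: str | Path, sep: str = ",") -> None:
    rows = [{"mixture_id": m.mixture_id, "ingredient_id": c.ingredient_id,
             "concentration_pct": _fmt(c.concentration),
             "ref_hazard": _fmt(m.ref_hazard.value if m.ref_hazard else None)}
            for m in mixtures for c in m.components]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
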