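"""Reading and screening per-study concentration tables.

Studies report maternal-transfer data in idiosyncratic layouts; ingestion maps
each source table onto :class:`~mtdb.records.StudyRecord` via a caller-supplied
column map, resolves compound naming against a shipped synonym table, and
applies the database's inclusion rules: bile observations are dropped (bile is
a liver product of highly variable composition), records flagged as outside
the instrument calibration range are dropped, and compound sums are kept only
when they contribute compounds not already reported individually in the same
study.  Every excluded record carries a reason code; every unparseable row a
diagnostic — nothing is silently discarded.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .harmonize import unit_factor
from .records import (
    QUAL_CENSORED,
    QUANT_CENSORED,
    TISSUES,
    UNCENSORED,
    RowDiagnostic,
    StudyRecord,
    with_fields,
)

# Exclusion reason codes
REASON_BILE = "bile"
REASON_DUPLICATE_SUM = "duplicate_sum"
REASON_CALIBRATION = "calibration"

_MANDATORY = (
    "study_id",
    "species",
    "subject_role",
    "subject_id",
    "tissue",
    "compound",
    "value",
    "unit",
    "basis",
)

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_BELOW_LOD_TOKENS = _TRUE_TOKENS | {
    "<lod",
    "<loq",
    "censored",
    "nd",
    "bdl",
    "<dl",
    "quant_censored",
    "qual_censored",
}

#: Congener-family prefixes normalized to a canonical numbered form,
#: e.g. "PCB-153" -> "PCB153", "PBDE 47" -> "BDE47".
_CONGENER_FAMILIES = {
    "pcb": "PCB",
    "cb": "PCB",
    "bde": "BDE",
    "pbde": "BDE",
    "pbb": "PBB",
}

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def _normalize_key(name: str) -> str:
    return _NON_ALNUM.sub("", name.lower())


def load_synonym_table(path: Optional[str | Path] = None) -> dict[str, str]:
    """Load the compound synonym table (shipped default; extensible).

    Returns a mapping from normalized (case/punctuation-insensitive) name to
    canonical compound_id.  Canonical ids always resolve to themselves so that
    canonicalization is idempotent.
    """
    if path is None:
        source = resources.files("mtdb.data").joinpath("synonyms.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    table: dict[str, str] = {}
    for row in rows:
        table[_normalize_key(row["synonym"])] = row["compound_id"]
    for canonical in list(table.values()):
        table.setdefault(_normalize_key(canonical), canonical)
    return table


def load_tissue_aliases(path: Optional[str | Path] = None) -> dict[str, str]:
    """Alias map from free-text tissue labels to the controlled vocabulary."""
    if path is None:
        source = resources.files("mtdb.data").joinpath("tissue_aliases.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    aliases = {_normalize_key(r["alias"]): r["tissue"] for r in rows}
    for t in TISSUES:
        aliases.setdefault(_normalize_key(t), t)
    return aliases


def canonicalize_compound(
    compound_raw: str, synonym_table: Mapping[str, str]
) -> tuple[str, bool]:
    """Resolve a published compound name to a canonical identifier.

    Lookup is case- and punctuation-insensitive.  Numbered congeners
    (PCB/BDE/PBB families) are normalized by pattern; anything else must match
    the synonym table.  Unmatched names are returned as-is with a False flag —
    never guessed.
    """
    if not compound_raw or not compound_raw.strip():
        raise ValueError("empty compound name")
    raw = compound_raw.strip()
    key = _normalize_key(raw)
    if key in synonym_table:
        return synonym_table[key], True
    m = re.fullmatch(r"([a-z]+)0*(\d+)", key)
    if m and m.group(1) in _CONGENER_FAMILIES:
        return f"{_CONGENER_FAMILIES[m.group(1)]}{int(m.group(2))}", True
    return raw, False


def canonicalize_records(
    records: Iterable[StudyRecord], synonym_table: Mapping[str, str]
) -> list[StudyRecord]:
    """Apply canonicalize_compound to every record (and its sum/coelution members)."""
    out = []
    for r in records:
        cid, resolved = canonicalize_compound(r.compound_raw, synonym_table)
        members = tuple(
            canonicalize_compound(m, synonym_table)[0] for m in r.members
        )
        out.append(
            with_fields(r, compound_id=cid, compound_resolved=resolved, members=members)
        )
    return out


# -- reading -----------------------------------------------------------------


def _parse_float(token: object) -> Optional[float]:
    if token is None:
        return None
    s = str(token).strip()
    if not s or s.lower() in {"na", "nan", "none"}:
        return None
    v = float(s)
    if math.isnan(v):
        return None
    return v


def _parse_bool(token: object) -> bool:
    if token is None:
        return False
    if isinstance(token, bool):
        return token
    return str(token).strip().lower() in _TRUE_TOKENS


def read_study_table(
    path: str | Path,
    column_map: Mapping[str, str],
    *,
    tissue_aliases: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> tuple[list[StudyRecord], list[RowDiagnostic]]:
    """Read one study's delimited table into StudyRecords.

    ``column_map`` maps canonical field names to the file's column headers;
    ``study_id, species, subject_role, subject_id, tissue, compound, value,
    unit, basis`` are mandatory (a missing mapping or column is a hard error).
    Optional fields: ``censored`` (below-LOD flag), ``lod``, ``mother_id``,
    ``n_pooled``, ``aggregation``, ``compound_class``, ``is_sum``,
    ``is_coelution``, ``members``, ``lipid_fraction_reported``,
    ``out_of_calibration``.

    Rows with an unparseable mandatory field (unknown tissue token, value that
    is not a number, inconsistent censoring flags) are excluded from the
    output but reported in the returned diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [f for f in _MANDATORY if f not in column_map]
    if missing:
        raise ValueError(f"column_map lacks mandatory fields: {missing}")
    absent = [c for c in column_map.values() if c not in frame.columns]
    if absent:
        raise ValueError(f"mandatory columns missing from {path.name}: {absent}")

    if tissue_aliases is None:
        tissue_aliases = load_tissue_aliases()

    def get(row, field, default=""):
        col = column_map.get(field)
        return row[col] if col is not None and col in row else default

    records: list[StudyRecord] = []
    diagnostics: list[RowDiagnostic] = []
    for idx, row in frame.iterrows():
        try:
            tissue_raw = str(get(row, "tissue")).strip()
            tissue = tissue_aliases.get(_normalize_key(tissue_raw))
            if tissue is None:
                raise ValueError(f"unknown tissue token {tissue_raw!r}")

            unit = str(get(row, "unit")).strip()
            unit_factor(unit)  # unknown unit token -> per-row diagnostic

            value = _parse_float(get(row, "value"))
            lod = _parse_float(get(row, "lod"))
            below_lod = str(get(row, "censored")).strip().lower() in _BELOW_LOD_TOKENS
            if below_lod and value is not None:
                raise ValueError("row flagged below-LOD but carries a value")
            if below_lod:
                censoring = QUANT_CENSORED if lod is not None else QUAL_CENSORED
            else:
                if value is None:
                    raise ValueError("row has neither a value nor a below-LOD flag")
                censoring = UNCENSORED

            members_raw = str(get(row, "members")).strip()
            members = tuple(m.strip() for m in members_raw.split("|") if m.strip())
            n_pooled = _parse_float(get(row, "n_pooled"))
            role = str(get(row, "subject_role")).strip().lower()
            mother_id = str(get(row, "mother_id")).strip() or None
            if role == "mother" and mother_id is None:
                mother_id = str(get(row, "subject_id")).strip()

            record = StudyRecord(
                study_id=str(get(row, "study_id")).strip(),
                species=str(get(row, "species")).strip(),
                subject_role=role,
                subject_id=str(get(row, "subject_id")).strip(),
                tissue=tissue,
                compound_raw=str(get(row, "compound")).strip(),
                unit=unit,
                basis=str(get(row, "basis")).strip().lower(),
                value=value,
                censoring=censoring,
                lod=lod if censoring != QUAL_CENSORED else None,
                compound_class=str(get(row, "compound_class", "other")).strip()
                or "other",
                mother_id=mother_id,
                n_pooled=int(n_pooled) if n_pooled else 1,
                aggregation=str(get(row, "aggregation", "individual")).strip()
                or "individual",
                is_sum=_parse_bool(get(row, "is_sum")),
                is_coelution=_parse_bool(get(row, "is_coelution")),
                members=members,
                lipid_fraction_reported=_parse_float(
                    get(row, "lipid_fraction_reported")
                ),
                out_of_calibration=_parse_bool(get(row, "out_of_calibration")),
            )
        except (ValueError, KeyError) as exc:
            diagnostics.append(RowDiagnostic(row=int(idx), field="row", message=str(exc)))
            continue
        records.append(record)
    return records, diagnostics


# -- screening ---------------------------------------------------------------


@dataclass(frozen=True)
class ExcludedRecord:
    record: StudyRecord
    reason: str


def apply_exclusion_rules(
    records: Sequence[StudyRecord],
) -> tuple[list[StudyRecord], list[ExcludedRecord]]:
    """Partition records into (kept, excluded-with-reason).

    Rules, in order: bile tissue; out-of-calibration flag; compound sums whose
    members are all already reported individually within the same study
    (avoiding double counting).  kept + excluded is always a partition of the
    input.
    """
    individually_reported: dict[str, set[str]] = {}
    for r in records:
        if not r.is_sum:
            cid = r.compound_id or r.compound_raw
            individually_reported.setdefault(r.study_id, set()).add(cid)

    kept: list[StudyRecord] = []
    excluded: list[ExcludedRecord] = []
    for r in records:
        if r.tissue == "bile":
            excluded.append(ExcludedRecord(r, REASON_BILE))
        elif r.out_of_calibration:
            excluded.append(ExcludedRecord(r, REASON_CALIBRATION))
        elif (
            r.is_sum
            and r.members
            and set(r.members) <= individually_reported.get(r.study_id, set())
        ):
            excluded.append(ExcludedRecord(r, REASON_DUPLICATE_SUM))
        else:
            kept.append(r)
    return kept, excluded


# -- group-level aggregation -------------------------------------------------


@dataclass(frozen=True)
class AggregationResult:
    value: float
    aggregation: str
    n_pooled: int
    diagnostic: Optional[str] = None


def select_aggregation(
    values_for_group: Sequence[float], reported: str = "geometric_mean"
) -> AggregationResult:
    """Summarize a group-reported set of concentrations.

    Individual data are always preferred upstream; this fires only when a
    study reports group-level data.  The geometric mean is preferred; with any
    zero or negative member it falls back to the arithmetic mean, with a
    diagnostic.  ``reported='arithmetic_mean'`` honours a study that provides
    only an arithmetic mean.
    """
    values = list(values_for_group)
    if not values:
        raise ValueError("cannot aggregate an empty group")
    n = len(values)
    if reported == "arithmetic_mean":
        return AggregationResult(sum(values) / n, "arithmetic_mean", n)
    if any(v <= 0 for v in values):
        return AggregationResult(
            sum(values) / n,
            "arithmetic_mean",
            n,
            diagnostic="geometric mean undefined for non-positive member; "
            "fell back to arithmetic mean",
        )
    log_mean = sum(math.log(v) for v in values) / n
    return AggregationResult(math.exp(log_mean), "geometric_mean", n)
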