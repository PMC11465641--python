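"""Domain types for the maternal-transfer database.

One *data point* is a single concentration observation: one compound in one
tissue of one individual (or pooled group of individuals).  A record moves
through the pipeline as an extracted :class:`StudyRecord` (value as published,
in the source study's unit and measurement basis) and becomes a
:class:`HarmonizedRecord` once expressed in ng/g on wet-weight and
lipid-normalized bases.

Censoring is three-state throughout: an observation is *uncensored* (an exact
value), *quantitatively censored* (below a known limit of detection, so the
value lies in the interval [0, LOD]) or *qualitatively censored* (below an
unreported limit, carrying no quantitative information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

# -- controlled vocabularies -------------------------------------------------

UNCENSORED = "uncensored"
QUANT_CENSORED = "quant_censored"
QUAL_CENSORED = "qual_censored"
CENSORING_STATES = (UNCENSORED, QUANT_CENSORED, QUAL_CENSORED)

MOTHER = "mother"
OFFSPRING = "offspring"
ROLES = (MOTHER, OFFSPRING)

TISSUES = (
    "whole_egg",
    "yolk",
    "albumen",
    "follicle",
    "hatchling_blood",
    "fat",
    "liver",
    "whole_blood",
    "plasma",
    "muscle",
    "kidney",
    "skin",
    "intestine",
    "stomach",
    "spleen",
    "heart",
    "lung",
    "bile",
    "other",
)

#: Matrices in which offspring burdens are measured.
OFFSPRING_MATRICES = ("whole_egg", "yolk", "albumen", "follicle", "hatchling_blood")

COMPOUND_CLASSES = (
    "PCB",
    "OCP",
    "HFR_BFR",
    "HFR_PFR",
    "PAH",
    "phthalate",
    "alt_plasticizer",
    "CP",
    "PFAS",
    "other",
)

BASES = ("wet", "dry", "lipid")

AGGREGATIONS = ("individual", "geometric_mean", "arithmetic_mean")

LIPID_SOURCES = (
    "study_reported",
    "same_species_literature",
    "related_species_literature",
)


# -- records -----------------------------------------------------------------


@dataclass(frozen=True)
class StudyRecord:
    """One extracted observation, exactly as published."""

    study_id: str
    species: str
    subject_role: str  # mother | offspring
    subject_id: str
    tissue: str
    compound_raw: str
    unit: str
    basis: str  # wet | dry | lipid
    value: Optional[float] = None
    censoring: str = UNCENSORED
    lod: Optional[float] = None
    compound_id: Optional[str] = None
    compound_resolved: bool = False
    compound_class: str = "other"
    mother_id: Optional[str] = None  # linkage; equals subject_id for mothers
    n_pooled: int = 1
    aggregation: str = "individual"
    is_sum: bool = False
    is_coelution: bool = False
    members: tuple[str, ...] = ()
    lipid_fraction_reported: Optional[float] = None
    out_of_calibration: bool = False

    def __post_init__(self) -> None:
        if self.subject_role not in ROLES:
            raise ValueError(f"unknown subject_role: {self.subject_role!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue: {self.tissue!r}")
        if self.basis not in BASES:
            raise ValueError(f"unknown basis: {self.basis!r}")
        if self.censoring not in CENSORING_STATES:
            raise ValueError(f"unknown censoring state: {self.censoring!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")
        if self.censoring == QUANT_CENSORED and self.lod is None:
            raise ValueError("quant_censored record requires an LOD")
        if self.censoring == QUAL_CENSORED and self.lod is not None:
            raise ValueError("qual_censored record cannot carry an LOD")
        if self.censoring == UNCENSORED and self.value is None:
            raise ValueError("uncensored record requires a value")
        if self.value is not None and self.value < 0:
            raise ValueError("concentration must be non-negative")
        if self.lod is not None and self.lod < 0:
            raise ValueError("LOD must be non-negative")
        if self.n_pooled < 1:
            raise ValueError("n_pooled must be >= 1")
        if self.is_sum and len(self.members) < 2:
            raise ValueError("a sum record must list >= 2 member compounds")
        if self.lipid_fraction_reported is not None and not (
            0.0 <= self.lipid_fraction_reported <= 1.0
        ):
            raise ValueError("lipid_fraction_reported must lie in [0, 1]")


@dataclass(frozen=True)
class HarmonizedRecord:
    """A StudyRecord expressed in ng/g, wet-weight and lipid-normalized.

    For quantitatively censored records the ``conc_*`` fields are None and the
    ``lod_*`` fields bound the interval [0, LOD]; qualitatively censored
    records carry no numeric fields at all.  ``conversion_trace`` lists each
    applied transform in order, e.g. ``unit:µg/g->ng/g(x1000)``.
    """

    record: StudyRecord
    conc_ng_g_ww: Optional[float] = None
    conc_ng_g_lw: Optional[float] = None
    lod_ng_g_ww: Optional[float] = None
    lod_ng_g_lw: Optional[float] = None
    lipid_fraction_used: Optional[float] = None
    lipid_source: Optional[str] = None
    conversion_trace: tuple[str, ...] = ()

    @property
    def censoring(self) -> str:
        return self.record.censoring

    def __post_init__(self) -> None:
        if (
            self.conc_ng_g_ww is not None
            and self.conc_ng_g_lw is not None
            and self.lipid_fraction_used
        ):
            expected = self.conc_ng_g_ww / self.lipid_fraction_used
            if not math.isclose(self.conc_ng_g_lw, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("conc_ng_g_lw inconsistent with conc_ng_g_ww / lipid fraction")


@dataclass(frozen=True)
class RowDiagnostic:
    """A per-row problem report; rows are reported, never silently dropped."""

    row: int | str
    field: str
    message: str


# -- lookup-table entries ----------------------------------------------------


@dataclass(frozen=True)
class LipidEntry:
    species: str
    tissue: str
    lipid_fraction: float
    source: str  # same_species_literature | related_species_literature resolved at lookup
    reference: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.lipid_fraction <= 1.0):
            raise ValueError("lipid_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class WaterEntry:
    species: str
    tissue: str
    water_fraction: float
    reference: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_fraction < 1.0):
            raise ValueError("water_fraction must lie in [0, 1)")


# -- DataFrame bridging ------------------------------------------------------

_LIST_SEP = "|"


def records_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Flatten StudyRecords into a DataFrame (members joined with '|')."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(StudyRecord)}
        d["members"] = _LIST_SEP.join(r.members)
        rows.append(d)
    cols = [f.name for f in fields(StudyRecord)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[StudyRecord]:
    records = []
    for _, row in frame.iterrows():
        d = row.to_dict()
        members = d.get("members", "")
        if isinstance(members, str):
            d["members"] = tuple(m for m in members.split(_LIST_SEP) if m)
        for key in ("value", "lod", "lipid_fraction_reported", "mother_id", "compound_id"):
            if key in d and pd.isna(d[key]):
                d[key] = None
        records.append(StudyRecord(**d))
    return records


def harmonized_to_frame(records: Sequence[HarmonizedRecord]) -> pd.DataFrame:
    """Flatten harmonized records: all StudyRecord metadata plus ng/g columns."""
    rows = []
    for h in records:
        d = {f.name: getattr(h.record, f.name) for f in fields(StudyRecord)}
        d["members"] = _LIST_SEP.join(h.record.members)
        d.update(
            conc_ng_g_ww=h.conc_ng_g_ww,
            conc_ng_g_lw=h.conc_ng_g_lw,
            lod_ng_g_ww=h.lod_ng_g_ww,
            lod_ng_g_lw=h.lod_ng_g_lw,
            lipid_fraction_used=h.lipid_fraction_used,
            lipid_source=h.lipid_source,
            conversion_trace=";".join(h.conversion_trace),
        )
        rows.append(d)
    cols = [f.name for f in fields(StudyRecord)] + [
        "conc_ng_g_ww",
        "conc_ng_g_lw",
        "lod_ng_g_ww",
        "lod_ng_g_lw",
        "lipid_fraction_used",
        "lipid_source",
        "conversion_trace",
    ]
    return pd.DataFrame(rows, columns=cols)


def with_fields(record: StudyRecord, **changes) -> StudyRecord:
    """Functional update helper (records are frozen)."""
    return replace(record, **changes)
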