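"""Unit, basis and lipid harmonization of concentration records.

All concentrations (and their detection limits) are brought onto a common
ng/g scale, wet-weight records are lipid-normalized by dividing by the tissue
lipid fraction, and dry-weight records are first converted to wet weight via
the tissue water content (conc_wet = conc_dry x (1 - water_fraction)).  Lipid
fractions come from a strictly ordered fallback chain: the study's own
reported value, then a literature value for the same species and tissue, then
a literature value for an explicitly declared closely related species.

All transforms are exact rational scalings (computed through
:class:`fractions.Fraction`), so value and LOD follow the identical composed
map and censoring status is never altered: a quantitatively censored record
keeps its interval [0, LOD] shape, and a qualitatively censored record has no
numbers to transform at all.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .records import (
    QUAL_CENSORED,
    QUANT_CENSORED,
    HarmonizedRecord,
    LipidEntry,
    RowDiagnostic,
    StudyRecord,
    WaterEntry,
)

# -- unit conversion ---------------------------------------------------------

#: Exact factors to ng/g for the supported mass-ratio unit dialect.
#: ppm/ppb/ppt are read as mass ratios: ppm = µg/g, ppb = ng/g, ppt = pg/g.
_UNIT_FACTORS: dict[str, Fraction] = {
    "ng/g": Fraction(1),
    "ug/g": Fraction(1000),
    "ug/kg": Fraction(1),
    "mg/kg": Fraction(1000),
    "ng/kg": Fraction(1, 1000),
    "pg/g": Fraction(1, 1000),
    "ppm": Fraction(1000),
    "ppb": Fraction(1),
    "ppt": Fraction(1, 1000),
}


def _normalize_unit(unit: str) -> str:
    return unit.strip().lower().replace("µ", "u").replace("μ", "u").replace(" ", "")


def unit_factor(unit: str) -> Fraction:
    """Exact rational factor taking ``unit`` to ng/g; raises on unknown units."""
    token = _normalize_unit(unit)
    if token not in _UNIT_FACTORS:
        raise ValueError(f"unsupported concentration unit: {unit!r}")
    return _UNIT_FACTORS[token]


def convert_unit(value: float, unit: str) -> float:
    """Convert a concentration in ``unit`` to ng/g."""
    if value < 0:
        raise ValueError("concentration must be non-negative")
    return float(Fraction(value) * unit_factor(unit))


def dry_to_wet(conc_dry: float, water_fraction: float) -> float:
    """Convert ng/g dry weight to ng/g wet weight.

    The analyte mass sits in the dry matter, so per gram of wet tissue the
    concentration scales by the dry-matter fraction (1 - water_fraction).
    """
    if not (0.0 <= water_fraction < 1.0):
        raise ValueError("water_fraction must lie in [0, 1)")
    return float(Fraction(conc_dry) * (1 - Fraction(water_fraction)))


def lipid_normalize(conc_wet: float, lipid_fraction: float) -> float:
    """Convert ng/g wet weight to ng/g lipid weight (divide by lipid fraction)."""
    if not (0.0 < lipid_fraction <= 1.0):
        raise ValueError("lipid_fraction must lie in (0, 1]")
    return float(Fraction(conc_wet) / Fraction(lipid_fraction))


# -- lookup tables -----------------------------------------------------------


def load_lipid_table(path: str | Path) -> list[LipidEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [
            LipidEntry(
                species=row["species"],
                tissue=row["tissue"],
                lipid_fraction=float(row["lipid_fraction"]),
                source=row.get("source", "same_species_literature"),
                reference=row.get("reference", ""),
            )
            for row in csv.DictReader(fh)
        ]


def load_water_table(path: str | Path) -> list[WaterEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [
            WaterEntry(
                species=row["species"],
                tissue=row["tissue"],
                water_fraction=float(row["water_fraction"]),
                reference=row.get("reference", ""),
            )
            for row in csv.DictReader(fh)
        ]


def load_relatedness_map(path: str | Path) -> dict[str, list[str]]:
    """Explicit species-relatedness map for the lipid fallback chain."""
    out: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["species"], []).append(row["related_species"])
    return out


def default_relatedness_map() -> dict[str, list[str]]:
    from importlib import resources

    source = resources.files("mtdb.data").joinpath("species_relatives.csv")
    out: dict[str, list[str]] = {}
    for row in csv.DictReader(source.read_text(encoding="utf-8").splitlines()):
        out.setdefault(row["species"], []).append(row["related_species"])
    return out


@dataclass(frozen=True)
class LipidLookup:
    lipid_fraction: float
    source: str
    reference: str = ""


def lookup_lipid_fraction(
    species: str,
    tissue: str,
    record: Optional[StudyRecord],
    lipid_table: Sequence[LipidEntry],
    relatedness: Optional[Mapping[str, Sequence[str]]] = None,
) -> Optional[LipidLookup]:
    """Resolve a tissue lipid fraction through the ordered fallback chain.

    study_reported -> same-species literature -> related-species literature.
    Returns None when no level yields a value; the caller keeps the record
    un-normalized (still usable for wet-weight analyses) with a diagnostic.
    """
    if record is not None and record.lipid_fraction_reported is not None:
        if record.lipid_fraction_reported > 0:
            return LipidLookup(record.lipid_fraction_reported, "study_reported")
    for entry in lipid_table:
        if entry.species == species and entry.tissue == tissue:
            return LipidLookup(
                entry.lipid_fraction, "same_species_literature", entry.reference
            )
    if relatedness:
        for relative in relatedness.get(species, ()):
            for entry in lipid_table:
                if entry.species == relative and entry.tissue == tissue:
                    return LipidLookup(
                        entry.lipid_fraction,
                        "related_species_literature",
                        entry.reference,
                    )
    return None


def _lookup_water_fraction(
    species: str, tissue: str, water_table: Sequence[WaterEntry]
) -> Optional[WaterEntry]:
    for entry in water_table:
        if entry.species == species and entry.tissue == tissue:
            return entry
    return None


# -- record harmonization ----------------------------------------------------


def harmonize_record(
    record: StudyRecord,
    lipid_table: Sequence[LipidEntry],
    water_table: Sequence[WaterEntry] = (),
    relatedness: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[HarmonizedRecord, list[RowDiagnostic]]:
    """Express one record in ng/g wet-weight and lipid-normalized bases.

    Value and LOD pass through the identical composed map
    (unit -> [dry->wet] -> [lipid]); the order is recorded in
    ``conversion_trace``.  Censoring is untouched: qualitatively censored
    records come out with no numeric fields, quantitatively censored records
    with transformed LODs only.
    """
    diags: list[RowDiagnostic] = []
    rid = f"{record.study_id}/{record.subject_id}/{record.compound_raw}"

    if record.censoring == QUAL_CENSORED:
        return HarmonizedRecord(record=record, conversion_trace=()), diags

    trace: list[str] = []

    def apply_chain(x: Optional[float], chain) -> Optional[float]:
        if x is None:
            return None
        for f in chain:
            x = f(x)
        return x

    chain = []
    factor = unit_factor(record.unit)
    chain.append(lambda v, f=factor: float(Fraction(v) * f))
    trace.append(f"unit:{record.unit}->ng/g(x{factor})")

    basis = record.basis
    if basis == "dry":
        water = _lookup_water_fraction(record.species, record.tissue, water_table)
        if water is None:
            diags.append(
                RowDiagnostic(
                    row=rid,
                    field="basis",
                    message="dry-weight record without a water-content entry; "
                    "left unconverted",
                )
            )
            return HarmonizedRecord(record=record, conversion_trace=tuple(trace)), diags
        wf = water.water_fraction
        chain.append(lambda v, wf=wf: dry_to_wet(v, wf))
        trace.append(f"dry->wet(x{1 - wf:g})")
        basis = "wet"

    lookup = lookup_lipid_fraction(
        record.species, record.tissue, record, lipid_table, relatedness
    )

    value = record.value if record.censoring != QUANT_CENSORED else None
    lod = record.lod

    if basis == "lipid":
        conc_lw = apply_chain(value, chain)
        lod_lw = apply_chain(lod, chain)
        if lookup is None:
            diags.append(
                RowDiagnostic(
                    row=rid,
                    field="lipid_fraction",
                    message="lipid-basis record without a lipid fraction; "
                    "wet-weight value unavailable",
                )
            )
            return (
                HarmonizedRecord(
                    record=record,
                    conc_ng_g_lw=conc_lw,
                    lod_ng_g_lw=lod_lw,
                    conversion_trace=tuple(trace),
                ),
                diags,
            )
        lf = lookup.lipid_fraction
        trace.append(f"lipid->wet(x{lf:g})")
        to_ww = lambda v: float(Fraction(v) * Fraction(lf))  # noqa: E731
        return (
            HarmonizedRecord(
                record=record,
                conc_ng_g_ww=to_ww(conc_lw) if conc_lw is not None else None,
                conc_ng_g_lw=conc_lw,
                lod_ng_g_ww=to_ww(lod_lw) if lod_lw is not None else None,
                lod_ng_g_lw=lod_lw,
                lipid_fraction_used=lf,
                lipid_source=lookup.source,
                conversion_trace=tuple(trace),
            ),
            diags,
        )

    # wet basis
    conc_ww = apply_chain(value, chain)
    lod_ww = apply_chain(lod, chain)
    if lookup is None:
        diags.append(
            RowDiagnostic(
                row=rid,
                field="lipid_fraction",
                message="no lipid fraction at any fallback level; kept on "
                "wet-weight basis only",
            )
        )
        return (
            HarmonizedRecord(
                record=record,
                conc_ng_g_ww=conc_ww,
                lod_ng_g_ww=lod_ww,
                conversion_trace=tuple(trace),
            ),
            diags,
        )
    lf = lookup.lipid_fraction
    trace.append(f"lipid/{lf:g}")
    return (
        HarmonizedRecord(
            record=record,
            conc_ng_g_ww=conc_ww,
            conc_ng_g_lw=lipid_normalize(conc_ww, lf) if conc_ww is not None else None,
            lod_ng_g_ww=lod_ww,
            lod_ng_g_lw=lipid_normalize(lod_ww, lf) if lod_ww is not None else None,
            lipid_fraction_used=lf,
            lipid_source=lookup.source,
            conversion_trace=tuple(trace),
        ),
        diags,
    )


def harmonize_table(
    records: Sequence[StudyRecord],
    lipid_table: Sequence[LipidEntry],
    water_table: Sequence[WaterEntry] = (),
    relatedness: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[HarmonizedRecord], list[RowDiagnostic]]:
    """Harmonize every record; diagnostics are pooled, order preserved."""
    harmonized: list[HarmonizedRecord] = []
    diagnostics: list[RowDiagnostic] = []
    for record in records:
        h, diags = harmonize_record(record, lipid_table, water_table, relatedness)
        harmonized.append(h)
        diagnostics.extend(diags)
    return harmonized, diagnostics
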