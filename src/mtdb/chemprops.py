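"""Molecular-property annotation of the studied compounds.

Descriptors (log Kow, molecular weight, complexity, heavy-atom count, H-bond
donors/acceptors, TPSA, formal charge, rotatable bonds) are consumed from
local property tables — snapshots of PubChem descriptors and KOWWIN
octanol-water partition coefficients — never queried live.  log Kow follows a
provenance policy: an experimental value wins over a model estimate, and an
explicit override table covers compound families absent from the estimation
model (chlorinated paraffins) and special coelutions.

Coelutions (compounds inseparable by the analytical method) receive a
descriptor only when every contributing compound has the same value; compound
sums never receive descriptors, since a sum cannot be tied to one molecular
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import StudyRecord

#: Descriptors carried for every compound; ints are exact, reals compared to 1e-6.
INT_DESCRIPTORS = (
    "heavy_atom_count",
    "h_bond_donors",
    "h_bond_acceptors",
    "formal_charge",
    "rotatable_bonds",
)
REAL_DESCRIPTORS = ("log_kow", "molecular_weight", "complexity", "tpsa")
DESCRIPTORS = REAL_DESCRIPTORS + INT_DESCRIPTORS

#: Agreement tolerance for real-valued descriptors across coeluting compounds.
COELUTION_TOL = 1e-6


@dataclass(frozen=True)
class CompoundProperty:
    """Descriptor set for one compound; None marks an unassigned descriptor."""

    compound_id: str
    log_kow: Optional[float] = None
    kow_provenance: str = "unassigned"  # experimental | estimated | override | unassigned
    molecular_weight: Optional[float] = None
    complexity: Optional[float] = None
    heavy_atom_count: Optional[int] = None
    h_bond_donors: Optional[int] = None
    h_bond_acceptors: Optional[int] = None
    tpsa: Optional[float] = None
    formal_charge: Optional[int] = None
    rotatable_bonds: Optional[int] = None

    def descriptor(self, name: str):
        return getattr(self, name)

    @property
    def is_fully_unassigned(self) -> bool:
        return all(getattr(self, d) is None for d in DESCRIPTORS)


def load_property_table(path: str | Path) -> pd.DataFrame:
    """Property table keyed by compound_id.

    Expected columns: ``compound_id``, ``log_kow_experimental``,
    ``log_kow_estimated`` and the descriptor columns; missing cells stay NaN.
    """
    frame = pd.read_csv(path)
    return frame.set_index("compound_id")


def load_override_table(path: str | Path) -> pd.DataFrame:
    """Override table: columns compound_key, descriptor, value, reference.

    ``compound_key`` is a single compound_id or a '+'-joined sorted member
    set for a coelution (e.g. ``PCB151+PCB82``).
    """
    return pd.read_csv(path)


def coelution_key(members: Iterable[str]) -> str:
    return "+".join(sorted(members))


def _override_value(
    overrides: Optional[pd.DataFrame], key: str, descriptor: str
) -> Optional[float]:
    if overrides is None or overrides.empty:
        return None
    hit = overrides[
        (overrides["compound_key"] == key) & (overrides["descriptor"] == descriptor)
    ]
    if hit.empty:
        return None
    return float(hit["value"].iloc[0])


def _cell(table: pd.DataFrame, cid: str, column: str) -> Optional[float]:
    if column not in table.columns or cid not in table.index:
        return None
    v = table.at[cid, column]
    if pd.isna(v):
        return None
    return float(v)


def attach_properties(
    compound_id: str,
    property_table: pd.DataFrame,
    override_table: Optional[pd.DataFrame] = None,
) -> CompoundProperty:
    """Assemble one compound's descriptors under the provenance policy.

    log Kow: experimental > estimated > override; absence everywhere leaves
    the descriptor unassigned (a recorded state, not an error).
    """
    kow: Optional[float] = None
    provenance = "unassigned"
    for column, label in (
        ("log_kow_experimental", "experimental"),
        ("log_kow_estimated", "estimated"),
    ):
        v = _cell(property_table, compound_id, column)
        if v is not None:
            kow, provenance = v, label
            break
    if kow is None:
        v = _override_value(override_table, compound_id, "log_kow")
        if v is not None:
            kow, provenance = v, "override"

    values: dict[str, Optional[float]] = {}
    for d in DESCRIPTORS:
        if d == "log_kow":
            continue
        v = _cell(property_table, compound_id, d)
        if v is None:
            v = _override_value(override_table, compound_id, d)
        values[d] = v
    for d in INT_DESCRIPTORS:
        if values.get(d) is not None:
            values[d] = int(round(values[d]))
    return CompoundProperty(
        compound_id=compound_id, log_kow=kow, kow_provenance=provenance, **values
    )


def resolve_coelution(
    members: Sequence[str],
    property_table: pd.DataFrame,
    override_table: Optional[pd.DataFrame] = None,
) -> CompoundProperty:
    """Descriptors for a coelution: assigned iff all members agree.

    Integer descriptors must match exactly; real-valued descriptors within
    ``COELUTION_TOL``.  A member missing a descriptor leaves it unassigned.
    Explicit override entries for the member set (experimental measurements of
    the combined peak) take precedence.  Symmetric in member order.
    """
    if len(members) < 2:
        raise ValueError("a coelution needs >= 2 member compounds")
    key = coelution_key(members)
    member_props = [attach_properties(m, property_table, override_table) for m in members]

    values: dict[str, Optional[float]] = {}
    provenance = "unassigned"
    for d in DESCRIPTORS:
        override = _override_value(override_table, key, d)
        if override is not None:
            values[d] = override
            if d == "log_kow":
                provenance = "override"
            continue
        vs = [p.descriptor(d) for p in member_props]
        if any(v is None for v in vs):
            values[d] = None
            continue
        if d in INT_DESCRIPTORS:
            agree = len({int(v) for v in vs}) == 1
        else:
            agree = max(vs) - min(vs) <= COELUTION_TOL
        values[d] = vs[0] if agree else None
        if d == "log_kow" and agree:
            provs = {p.kow_provenance for p in member_props}
            provenance = provs.pop() if len(provs) == 1 else "estimated"
    for d in INT_DESCRIPTORS:
        if values.get(d) is not None:
            values[d] = int(round(values[d]))
    kow = values.pop("log_kow")
    return CompoundProperty(
        compound_id=key, log_kow=kow, kow_provenance=provenance, **values
    )


def sum_property_rule(record: StudyRecord) -> CompoundProperty:
    """A compound sum receives no molecular descriptors, ever."""
    if not record.is_sum:
        raise ValueError("sum_property_rule applies only to sum records")
    return CompoundProperty(compound_id=record.compound_id or record.compound_raw)


def annotate_record(
    record: StudyRecord,
    property_table: pd.DataFrame,
    override_table: Optional[pd.DataFrame] = None,
) -> CompoundProperty:
    """Route a record to the applicable descriptor rule (sum > coelution > single)."""
    if record.is_sum:
        return sum_property_rule(record)
    if record.is_coelution and record.members:
        return resolve_coelution(record.members, property_table, override_table)
    return attach_properties(
        record.compound_id or record.compound_raw, property_table, override_table
    )


# -- chemical-space summaries ------------------------------------------------


def chemical_space_summary(
    properties: Sequence[CompoundProperty],
    classes: Mapping[str, str],
    group_by_class: bool = True,
) -> pd.DataFrame:
    """Per-class descriptor statistics over unique compounds.

    Repeated entries for a compound_id are deduplicated before summarizing.
    Means/min/max cover assigned descriptor values only; the zero-value
    fractions (formal charge, H-bond donors/acceptors, TPSA) are computed over
    compounds with that descriptor assigned.
    """
    unique: dict[str, CompoundProperty] = {}
    for p in properties:
        unique.setdefault(p.compound_id, p)

    groups: dict[str, list[CompoundProperty]] = {}
    for cid, prop in unique.items():
        group = classes.get(cid, "other") if group_by_class else "all"
        groups.setdefault(group, []).append(prop)

    rows = []
    for group in sorted(groups):
        props = groups[group]
        row: dict[str, object] = {"group": group, "n_compounds": len(props)}
        for d in DESCRIPTORS:
            vals = [p.descriptor(d) for p in props if p.descriptor(d) is not None]
            if vals:
                row[f"{d}_mean"] = float(np.mean(vals))
                row[f"{d}_min"] = float(min(vals))
                row[f"{d}_max"] = float(max(vals))
                row[f"{d}_n"] = len(vals)
            else:
                row[f"{d}_mean"] = row[f"{d}_min"] = row[f"{d}_max"] = math.nan
                row[f"{d}_n"] = 0
        for d, label in (
            ("formal_charge", "fraction_zero_charge"),
            ("h_bond_donors", "fraction_zero_donors"),
            ("h_bond_acceptors", "fraction_zero_acceptors"),
            ("tpsa", "fraction_zero_tpsa"),
        ):
            vals = [p.descriptor(d) for p in props if p.descriptor(d) is not None]
            row[label] = (
                float(np.mean([v == 0 for v in vals])) if vals else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def missing_descriptor_share(properties: Sequence[CompoundProperty]) -> float:
    """Fraction of unique compounds with at least one missing descriptor."""
    unique: dict[str, CompoundProperty] = {}
    for p in properties:
        unique.setdefault(p.compound_id, p)
    if not unique:
        return math.nan
    n_missing = sum(
        any(p.descriptor(d) is None for d in DESCRIPTORS) for p in unique.values()
    )
    return n_missing / len(unique)
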