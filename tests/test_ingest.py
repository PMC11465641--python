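"""Ingestion: reading study tables, compound canonicalization, screening rules."""

import math
import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdb.ingest import (
    REASON_BILE,
    REASON_CALIBRATION,
    REASON_DUPLICATE_SUM,
    apply_exclusion_rules,
    canonicalize_compound,
    canonicalize_records,
    load_synonym_table,
    read_study_table,
    select_aggregation,
)
from mtdb.records import QUAL_CENSORED, QUANT_CENSORED, UNCENSORED, StudyRecord

COLUMN_MAP = {
    "study_id": "study",
    "species": "species",
    "subject_role": "role",
    "subject_id": "id",
    "tissue": "tissue",
    "compound": "compound",
    "value": "conc",
    "unit": "unit",
    "basis": "basis",
    "censored": "flag",
    "lod": "lod",
}


def write_csv(tmp_path, body):
    path = tmp_path / "study.csv"
    path.write_text(textwrap.dedent(body))
    return path


def test_read_study_table_identity(tmp_path):
    """Three clean rows become three records with fields mapped through."""
    path = write_csv(
        tmp_path,
        """\
        study,species,role,id,tissue,compound,conc,unit,basis,flag,lod
        S1,Chelonia mydas,mother,M1,liver,PCB153,12.5,ng/g,wet,,
        S1,Chelonia mydas,mother,M1,whole blood,p p DDE,3.1,ug/g,wet,,
        S1,Chelonia mydas,offspring,E1,egg,PCB153,8.0,ng/g,wet,,
        """,
    )
    records, diags = read_study_table(path, COLUMN_MAP)
    assert len(records) == 3 and not diags
    assert records[0].value == 12.5 and records[0].censoring == UNCENSORED
    # tissue aliases resolve to the controlled vocabulary
    assert records[1].tissue == "whole_blood"
    assert records[2].tissue == "whole_egg"
    # mothers are their own linkage anchor
    assert records[0].mother_id == "M1"


def test_below_lod_without_lod_is_qualitative(tmp_path):
    """A censoring flag with an empty LOD cell is a qualitatively censored value."""
    path = write_csv(
        tmp_path,
        """\
        study,species,role,id,tissue,compound,conc,unit,basis,flag,lod
        S1,Chelonia mydas,mother,M1,liver,PCB153,,ng/g,wet,<LOD,
        S1,Chelonia mydas,mother,M1,liver,PCB180,,ng/g,wet,<LOD,0.5
        """,
    )
    records, diags = read_study_table(path, COLUMN_MAP)
    assert not diags
    assert records[0].censoring == QUAL_CENSORED and records[0].lod is None
    assert records[1].censoring == QUANT_CENSORED and records[1].lod == 0.5


def test_bad_rows_reported_not_dropped_silently(tmp_path):
    """Unknown unit or tissue tokens produce per-row diagnostics, not records."""
    path = write_csv(
        tmp_path,
        """\
        study,species,role,id,tissue,compound,conc,unit,basis,flag,lod
        S1,Chelonia mydas,mother,M1,liver,PCB153,5.0,oz,wet,,
        S1,Chelonia mydas,mother,M1,gizzard,PCB153,5.0,ng/g,wet,,
        S1,Chelonia mydas,mother,M1,liver,PCB153,5.0,ng/g,wet,,
        """,
    )
    records, diags = read_study_table(path, COLUMN_MAP)
    assert len(records) == 1
    assert len(diags) == 2
    assert any("oz" in d.message for d in diags)
    assert any("gizzard" in d.message for d in diags)


def test_missing_mandatory_column_is_hard_error(tmp_path):
    path = write_csv(tmp_path, "study,species\nS1,x\n")
    with pytest.raises(ValueError):
        read_study_table(path, COLUMN_MAP)


# -- compound canonicalization ----------------------------------------------


@pytest.mark.parametrize(
    "a,b",
    [
        ("p,p'-DDE", "4,4'-DDE"),
        ("PCB-153", "pcb 153"),
        ("Hexachlorobenzene", "HCB"),
        ("perfluorooctane sulfonate", "PFOS"),
    ],
)
def test_synonyms_map_to_one_compound(synonyms, a, b):
    ca, ra = canonicalize_compound(a, synonyms)
    cb, rb = canonicalize_compound(b, synonyms)
    assert ra and rb and ca == cb


def test_congener_formatting(synonyms):
    assert canonicalize_compound("PCB-153", synonyms) == ("PCB153", True)
    assert canonicalize_compound("PBDE 47", synonyms) == ("BDE47", True)


def test_unmatched_name_flagged_never_guessed(synonyms):
    cid, resolved = canonicalize_compound("unknowncompoundX", synonyms)
    assert not resolved and cid == "unknowncompoundX"


def test_empty_name_is_error(synonyms):
    with pytest.raises(ValueError):
        canonicalize_compound("  ", synonyms)


def test_canonicalization_idempotent(synonyms):
    names = ["p,p'-DDE", "PCB-153", "unknowncompoundX", "Dieldrin", "BDE-99"]
    for name in names:
        once, _ = canonicalize_compound(name, synonyms)
        twice, _ = canonicalize_compound(once, synonyms)
        assert twice == once


# -- exclusion rules ---------------------------------------------------------


def rec(**kw):
    base = dict(
        study_id="S1",
        species="Chelonia mydas",
        subject_role="mother",
        subject_id="M1",
        tissue="liver",
        compound_raw="PCB153",
        compound_id="PCB153",
        unit="ng/g",
        basis="wet",
        value=1.0,
    )
    base.update(kw)
    return StudyRecord(**base)


def test_bile_and_calibration_excluded():
    records = [
        rec(tissue="bile"),
        rec(out_of_calibration=True),
        rec(),
    ]
    kept, excluded = apply_exclusion_rules(records)
    assert len(kept) == 1
    reasons = {e.reason for e in excluded}
    assert reasons == {REASON_BILE, REASON_CALIBRATION}


def test_duplicate_sum_rule_per_study():
    members_all_present = [
        rec(compound_id="p,p'-DDT", compound_raw="p,p'-DDT"),
        rec(compound_id="p,p'-DDE", compound_raw="p,p'-DDE"),
        rec(compound_id="p,p'-DDD", compound_raw="p,p'-DDD"),
        rec(
            compound_raw="sum-DDT",
            compound_id="sum-DDT",
            is_sum=True,
            members=("p,p'-DDT", "p,p'-DDE", "p,p'-DDD"),
        ),
    ]
    kept, excluded = apply_exclusion_rules(members_all_present)
    assert [e.reason for e in excluded] == [REASON_DUPLICATE_SUM]

    # a sum contributing a compound not reported individually is kept
    one_missing = members_all_present[:2] + [members_all_present[3]]
    kept, excluded = apply_exclusion_rules(one_missing)
    assert not excluded and len(kept) == 3

    # ...and the rule is scoped per study: the same members in another study
    # do not disqualify this study's sum
    other_study = [
        rec(study_id="S2", compound_id="p,p'-DDD", compound_raw="p,p'-DDD"),
        members_all_present[0],
        members_all_present[1],
        members_all_present[3],
    ]
    kept, excluded = apply_exclusion_rules(other_study)
    assert not excluded


def test_exclusion_conserves_records(default_dataset):
    """kept + excluded partitions the input (conservation)."""
    records = default_dataset.records
    kept, excluded = apply_exclusion_rules(records)
    assert len(kept) + len(excluded) == len(records)
    back = {id(r) for r in kept} | {id(e.record) for e in excluded}
    assert back == {id(r) for r in records}


# -- group aggregation -------------------------------------------------------


def test_geometric_mean_preferred():
    result = select_aggregation([10, 1000])
    assert result.aggregation == "geometric_mean"
    assert math.isclose(result.value, 100.0)
    assert result.n_pooled == 2


def test_zero_member_falls_back_to_arithmetic():
    result = select_aggregation([0, 10])
    assert result.aggregation == "arithmetic_mean"
    assert result.value == 5.0
    assert result.diagnostic is not None


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20))
def test_geometric_never_exceeds_arithmetic(values):
    geo = select_aggregation(values)
    arith = select_aggregation(values, reported="arithmetic_mean")
    assert geo.value <= arith.value * (1 + 1e-12)
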