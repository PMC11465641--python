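"""Unit/basis conversions, lipid lookup chain, and record harmonization."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdb.harmonize import (
    convert_unit,
    dry_to_wet,
    harmonize_record,
    harmonize_table,
    lipid_normalize,
    lookup_lipid_fraction,
)
from mtdb.records import (
    QUAL_CENSORED,
    QUANT_CENSORED,
    LipidEntry,
    StudyRecord,
    WaterEntry,
)

# Independent oracle: re-derive every factor from SI-prefix decomposition.
_PREFIX_G = {"pg": 1e-12, "ng": 1e-9, "ug": 1e-6, "mg": 1e-3}
_RATIO = {"ppm": 1e-6, "ppb": 1e-9, "ppt": 1e-12}


def oracle_factor(unit: str) -> float:
    u = unit.lower().replace("µ", "u").replace("μ", "u")
    if u in _RATIO:
        grams_per_gram = _RATIO[u]
    else:
        num, denom = u.split("/")
        grams_per_gram = _PREFIX_G[num] / {"g": 1.0, "kg": 1e3}[denom]
    return grams_per_gram / 1e-9  # ng/g per unit


ALL_UNITS = ["ng/g", "µg/g", "µg/kg", "mg/kg", "ng/kg", "pg/g", "ppm", "ppb", "ppt"]


@pytest.mark.parametrize(
    "value,unit,expected",
    [
        (1.0, "µg/g", 1000.0),
        (0.5, "mg/kg", 500.0),
        (2.0, "ppb", 2.0),
        (1.0, "ppm", 1000.0),
        (3.0, "ng/kg", 0.003),
    ],
)
def test_convert_unit_worked_examples(value, unit, expected):
    assert math.isclose(convert_unit(value, unit), expected, rel_tol=1e-12)


def test_convert_unit_matches_prefix_oracle():
    """All supported units agree with brute-force factor arithmetic on 1000 values."""
    rng = np.random.default_rng(42)
    values = rng.uniform(1e-6, 1e6, size=1000)
    for unit in ALL_UNITS:
        f = oracle_factor(unit)
        for v in values[::17]:  # spot sample per unit; full sweep in acceptance
            assert math.isclose(convert_unit(float(v), unit), v * f, rel_tol=1e-9)


def test_unknown_unit_names_token():
    with pytest.raises(ValueError, match="oz"):
        convert_unit(1.0, "oz")


def test_dry_to_wet():
    assert math.isclose(dry_to_wet(100.0, 0.667), 33.3, rel_tol=1e-9)
    assert dry_to_wet(5.0, 0.0) == 5.0
    assert dry_to_wet(0.0, 0.667) == 0.0
    with pytest.raises(ValueError):
        dry_to_wet(1.0, 1.0)


def test_lipid_normalize():
    assert math.isclose(lipid_normalize(50.0, 0.05), 1000.0, rel_tol=1e-12)
    assert lipid_normalize(7.0, 1.0) == 7.0
    assert lipid_normalize(0.0, 0.05) == 0.0
    with pytest.raises(ValueError):
        lipid_normalize(1.0, 0.0)
    with pytest.raises(ValueError):
        lipid_normalize(1.0, 1.5)


@settings(deadline=None, max_examples=200)
@given(
    conc=st.floats(min_value=1e-9, max_value=1e9),
    lf=st.floats(min_value=1e-4, max_value=1.0),
)
def test_lipid_normalization_round_trip(conc, lf):
    assert math.isclose(lipid_normalize(conc, lf) * lf, conc, rel_tol=1e-9)


# -- lipid lookup chain ------------------------------------------------------

LIPIDS = [
    LipidEntry("Chelonia mydas", "liver", 0.06, "same_species_literature"),
    LipidEntry("Caretta caretta", "whole_egg", 0.09, "same_species_literature"),
]
RELATED = {"Chelonia mydas": ["Caretta caretta"]}


def make_record(**kw):
    base = dict(
        study_id="S1",
        species="Chelonia mydas",
        subject_role="mother",
        subject_id="M1",
        tissue="liver",
        compound_raw="PCB153",
        unit="ng/g",
        basis="wet",
        value=50.0,
    )
    base.update(kw)
    return StudyRecord(**base)


def test_lookup_chain_strictly_ordered():
    reported = make_record(lipid_fraction_reported=0.04)
    hit = lookup_lipid_fraction("Chelonia mydas", "liver", reported, LIPIDS, RELATED)
    assert (hit.lipid_fraction, hit.source) == (0.04, "study_reported")

    hit = lookup_lipid_fraction("Chelonia mydas", "liver", make_record(), LIPIDS, RELATED)
    assert (hit.lipid_fraction, hit.source) == (0.06, "same_species_literature")

    egg = make_record(tissue="whole_egg", subject_role="offspring")
    hit = lookup_lipid_fraction("Chelonia mydas", "whole_egg", egg, LIPIDS, RELATED)
    assert (hit.lipid_fraction, hit.source) == (0.09, "related_species_literature")

    assert lookup_lipid_fraction("Chelonia mydas", "muscle", make_record(tissue="muscle"), LIPIDS, RELATED) is None


# -- record harmonization ----------------------------------------------------

WATER = [WaterEntry("Chelonia mydas", "whole_egg", 0.667)]
EGG_LIPID = [LipidEntry("Chelonia mydas", "whole_egg", 0.08, "same_species_literature")]


def test_worked_dry_weight_egg_conversion():
    """0.2 ug/g dry weight, 66.7% water, 8% lipid -> 66.6 ng/g ww, 832.5 ng/g lw."""
    record = make_record(
        subject_role="offspring", tissue="whole_egg", basis="dry", unit="µg/g", value=0.2
    )
    h, diags = harmonize_record(record, EGG_LIPID, WATER)
    assert not diags
    assert math.isclose(h.conc_ng_g_ww, 66.6, rel_tol=1e-9)
    assert math.isclose(h.conc_ng_g_lw, 832.5, rel_tol=1e-9)
    # dry->wet must precede lipid normalization in the applied chain
    trace = list(h.conversion_trace)
    assert trace.index(next(t for t in trace if t.startswith("dry->wet"))) < trace.index(
        next(t for t in trace if t.startswith("lipid"))
    )


def test_censored_lod_transforms_like_a_value():
    record = make_record(
        value=None,
        censoring=QUANT_CENSORED,
        lod=1.0,
        tissue="whole_egg",
        subject_role="offspring",
    )
    lipids = [LipidEntry("Chelonia mydas", "whole_egg", 0.05, "same_species_literature")]
    h, _ = harmonize_record(record, lipids)
    assert h.conc_ng_g_ww is None and h.conc_ng_g_lw is None
    assert math.isclose(h.lod_ng_g_lw, 20.0, rel_tol=1e-12)
    assert h.censoring == QUANT_CENSORED


def test_qualitative_record_keeps_no_numbers():
    record = make_record(value=None, censoring=QUAL_CENSORED, lod=None)
    h, _ = harmonize_record(record, LIPIDS)
    assert h.conc_ng_g_ww is None and h.conc_ng_g_lw is None
    assert h.lod_ng_g_ww is None and h.lod_ng_g_lw is None
    assert h.censoring == QUAL_CENSORED


def test_no_lipid_fraction_keeps_wet_weight_with_diagnostic():
    record = make_record(tissue="muscle")
    h, diags = harmonize_record(record, LIPIDS)
    assert h.conc_ng_g_ww == 50.0 and h.conc_ng_g_lw is None
    assert diags and "lipid" in diags[0].message


def test_harmonized_concentration_monotone_in_input():
    values = [1.0, 2.0, 5.0, 50.0, 500.0]
    out = [
        harmonize_record(make_record(value=v), LIPIDS)[0].conc_ng_g_lw for v in values
    ]
    assert all(a < b for a, b in zip(out, out[1:]))


def test_censoring_multiset_conserved(default_dataset, harmonized_default):
    """Harmonization never changes any record's censoring status."""
    before = Counter(r.censoring for r in default_dataset.records)
    harmonized, _ = harmonized_default
    after = Counter(h.censoring for h in harmonized)
    assert before == after


def test_lipid_basis_record_back_converts_to_wet():
    record = make_record(basis="lipid", value=1000.0)
    h, _ = harmonize_record(record, LIPIDS)
    assert h.conc_ng_g_lw == 1000.0
    assert math.isclose(h.conc_ng_g_ww, 60.0, rel_tol=1e-12)  # x 0.06 liver lipid
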