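"""Pairing, partition ratios, banding, summaries, correlations, Kow trends."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdb.records import QUANT_CENSORED, UNCENSORED
from mtdb.transfer import (
    band_counts,
    equilibrium_band,
    pair_mother_offspring,
    ratio_summary,
    ratio_vs_kow,
    tissue_correlations,
    transfer_ratio_value,
    transfer_ratios,
)


def db_row(role, subject, tissue, conc, mother="M1", compound="PCB153", censoring=UNCENSORED, study="S1"):
    return {
        "study_id": study,
        "species": "Malaclemys terrapin",
        "subject_role": role,
        "subject_id": subject,
        "mother_id": mother,
        "tissue": tissue,
        "compound_id": compound,
        "compound_class": "PCB",
        "censoring": censoring,
        "conc_ng_g_lw": conc,
        "conc_ng_g_ww": conc,
    }


def little_db():
    return pd.DataFrame(
        [
            db_row("mother", "M1", "liver", 100.0),
            db_row("offspring", "E1", "whole_egg", 50.0),
            db_row("offspring", "E2", "whole_egg", 100.0),
            db_row("offspring", "E3", "whole_egg", 200.0),
        ]
    )


def test_per_egg_pairing_counts():
    pairs, diags = pair_mother_offspring(little_db(), policy="per_egg")
    assert len(pairs) == 3 and diags.empty
    assert set(pairs["mother_tissue"]) == {"liver"}


def test_clutch_mean_pairing_uses_geometric_mean():
    pairs, _ = pair_mother_offspring(little_db(), policy="clutch_mean")
    assert len(pairs) == 1
    expected = (50.0 * 100.0 * 200.0) ** (1 / 3)
    assert math.isclose(pairs["c_offspring"].iloc[0], expected, rel_tol=1e-12)


def test_compound_only_in_eggs_yields_no_pairs():
    db = pd.DataFrame(
        [
            db_row("mother", "M1", "liver", 100.0, compound="PCB153"),
            db_row("offspring", "E1", "whole_egg", 50.0, compound="PCB180"),
        ]
    )
    pairs, _ = pair_mother_offspring(db)
    assert pairs.empty


def test_orphan_offspring_reported():
    db = pd.DataFrame(
        [
            db_row("mother", "M1", "liver", 100.0),
            db_row("offspring", "E1", "whole_egg", 50.0, mother="M99"),
        ]
    )
    pairs, diags = pair_mother_offspring(db)
    assert pairs.empty and len(diags) == 1


# -- ratios ------------------------------------------------------------------


@pytest.mark.parametrize(
    "c_mother,c_offspring,expected",
    [(100.0, 100.0, 0.0), (100.0, 1000.0, 1.0), (500.0, 50.0, -1.0)],
)
def test_ratio_values(c_mother, c_offspring, expected):
    assert math.isclose(transfer_ratio_value(c_mother, c_offspring), expected, abs_tol=1e-12)


@settings(deadline=None, max_examples=200)
@given(
    a=st.floats(min_value=1e-6, max_value=1e6),
    b=st.floats(min_value=1e-6, max_value=1e6),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_ratio_antisymmetric_and_scale_invariant(a, b, scale):
    r = transfer_ratio_value(a, b)
    assert math.isclose(transfer_ratio_value(b, a), -r, abs_tol=1e-9)
    # a common unit factor on both sides (a study-wide rescaling) cancels
    assert math.isclose(transfer_ratio_value(a * scale, b * scale), r, abs_tol=1e-9)


def test_censored_and_zero_pairs_skipped_with_reason():
    db = little_db()
    db.loc[1, "censoring"] = QUANT_CENSORED
    db.loc[1, "conc_ng_g_lw"] = np.nan
    db.loc[2, "conc_ng_g_lw"] = 0.0
    pairs, _ = pair_mother_offspring(db)
    ratios, skipped = transfer_ratios(pairs)
    assert len(ratios) == 1
    assert sorted(skipped["reason"]) == ["censored_offspring", "zero_concentration"]


def test_equilibrium_band_boundary_inclusive():
    assert equilibrium_band(0.3) == "within_10fold"
    assert equilibrium_band(1.0) == "within_10fold"
    assert equilibrium_band(-1.0) == "within_10fold"
    assert equilibrium_band(-1.7) == "below"
    assert equilibrium_band(1.2) == "above"
    with pytest.raises(ValueError):
        equilibrium_band(float("nan"))


def test_band_counts_totals():
    ratios = pd.DataFrame(
        {"R": [0.0, 0.5, 1.5, -2.0], "compound_class": ["PCB"] * 4}
    )
    out = band_counts(ratios, by=["compound_class"]).set_index("band")
    assert out.loc["within_10fold", "n"] == 2
    assert out.loc["above", "n"] == 1
    assert out.loc["below", "n"] == 1


# -- summaries ---------------------------------------------------------------


def ratio_frame(values, **keys):
    base = {"species": "s", "mother_tissue": "liver", "compound_class": "PCB"}
    base.update(keys)
    return pd.DataFrame([{**base, "R": v} for v in values])


def manual_quantile(xs, q):
    """Type-7 (linear interpolation) order-statistics oracle."""
    xs = sorted(xs)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def test_ratio_summary_three_points():
    out = ratio_summary(ratio_frame([-1.0, 0.0, 1.0]))
    row = out.iloc[0]
    assert row["median"] == 0.0
    # type-7 quartiles of {-1, 0, 1} interpolate to +/- 0.5
    assert (row["q1"], row["q3"]) == (-0.5, 0.5)
    assert row["iqr"] == 1.0
    assert row["n_outliers"] == 0


def test_single_ratio_collapses():
    row = ratio_summary(ratio_frame([0.37])).iloc[0]
    assert row["median"] == row["q1"] == row["q3"] == 0.37


def test_ratio_summary_matches_order_statistics_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        xs = rng.normal(0, 1, size=rng.integers(1, 40)).tolist()
        row = ratio_summary(ratio_frame(xs)).iloc[0]
        q1, med, q3 = (manual_quantile(xs, q) for q in (0.25, 0.5, 0.75))
        assert math.isclose(row["median"], med, abs_tol=1e-12)
        assert math.isclose(row["q1"], q1, abs_tol=1e-12)
        assert math.isclose(row["q3"], q3, abs_tol=1e-12)
        iqr = q3 - q1
        lo = max(min(xs), q1 - 1.5 * iqr)
        hi = min(max(xs), q3 + 1.5 * iqr)
        assert math.isclose(row["whisker_low"], lo, abs_tol=1e-12)
        assert math.isclose(row["whisker_high"], hi, abs_tol=1e-12)
        assert row["n_outliers"] == sum(1 for x in xs if x < lo or x > hi)


# -- tissue correlations -----------------------------------------------------


def mother_obs(subject, tissue, conc, compound):
    return db_row("mother", subject, tissue, conc, mother=subject, compound=compound)


def test_proportional_tissues_correlate_perfectly():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(30):
        c = float(10 ** rng.normal(2, 0.5))
        rows.append(mother_obs(f"M{i}", "liver", c, "PCB153"))
        rows.append(mother_obs(f"M{i}", "fat", 2 * c, "PCB153"))
    matrix, summary = tissue_correlations(pd.DataFrame(rows), min_pairs=10)
    assert len(matrix) == 1
    assert math.isclose(matrix["pearson"].iloc[0], 1.0, abs_tol=1e-12)
    assert math.isclose(summary["median"], 1.0, abs_tol=1e-12)


def test_independent_tissues_correlate_near_zero():
    rng = np.random.default_rng(9)
    rows = []
    for i in range(500):
        rows.append(mother_obs(f"M{i}", "liver", float(10 ** rng.normal(2, 0.5)), "PCB153"))
        rows.append(mother_obs(f"M{i}", "fat", float(10 ** rng.normal(2, 0.5)), "PCB153"))
    matrix, _ = tissue_correlations(pd.DataFrame(rows), min_pairs=10)
    assert abs(matrix["pearson"].iloc[0]) < 0.1


def test_below_min_pairs_entry_absent():
    rows = [
        mother_obs("M1", "liver", 10.0, "PCB153"),
        mother_obs("M1", "fat", 20.0, "PCB153"),
    ]
    matrix, summary = tissue_correlations(pd.DataFrame(rows), min_pairs=10)
    assert matrix.empty and summary["n_pairs"] == 0


# -- ratio vs Kow ------------------------------------------------------------

KOW = {"c1": 5.0, "c2": 6.0, "c3": 7.0, "c4": 8.0}


def kow_ratio_frame(fn, n_per=1):
    rows = []
    for cid, k in KOW.items():
        for _ in range(n_per):
            rows.append(
                {
                    "species": "s",
                    "mother_tissue": "liver",
                    "compound_class": "PCB",
                    "compound_id": cid,
                    "R": fn(k),
                }
            )
    return pd.DataFrame(rows)


def test_noiseless_line_recovered_exactly():
    out = ratio_vs_kow(kow_ratio_frame(lambda k: -0.2 * k + 1.0), KOW)
    row = out.iloc[0]
    assert math.isclose(row["slope"], -0.2, abs_tol=1e-12)
    assert math.isclose(row["intercept"], 1.0, abs_tol=1e-12)
    assert row["spearman"] == -1.0
    assert row["low_n"]  # n = 4 < 5


def test_flat_relation_slope_within_two_se_of_zero():
    rng = np.random.default_rng(21)
    frame = kow_ratio_frame(lambda k: float(rng.normal(0, 0.3)), n_per=50)
    row = ratio_vs_kow(frame, KOW).iloc[0]
    assert abs(row["slope"]) < 2 * row["slope_stderr"] + 1e-12
    assert not row["low_n"] and row["n"] == 200


def test_shared_kow_has_undefined_slope():
    frame = kow_ratio_frame(lambda k: 0.1)
    frame["compound_id"] = "c1"  # everyone shares one Kow
    row = ratio_vs_kow(frame, KOW).iloc[0]
    assert row["undefined_slope"] and math.isnan(row["slope"])
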