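"""Censoring typology and data-amount accounting.

Nondetects dominate field ecotoxicology tables; this module classifies every
observation as uncensored, quantitatively censored (below a *known* LOD — the
interval [0, LOD] still carries information) or qualitatively censored (below
an unreported limit — no quantitative information at all), and produces the
count tables used to audit how much usable data each species, tissue and
compound class actually contributes.  No imputation is performed anywhere.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .records import (
    QUAL_CENSORED,
    QUANT_CENSORED,
    UNCENSORED,
    StudyRecord,
)


def classify_censoring(
    value_present: bool, below_lod: bool, lod_present: bool
) -> str:
    """Deterministic three-state classification from the raw row flags."""
    if below_lod and value_present:
        raise ValueError("inconsistent flags: a below-LOD row cannot carry a value")
    if below_lod:
        return QUANT_CENSORED if lod_present else QUAL_CENSORED
    if not value_present:
        raise ValueError("a row without a below-LOD flag must carry a value")
    return UNCENSORED


def classify_record(record: StudyRecord) -> str:
    """Re-derive the censoring state of an ingested record from its fields."""
    below = record.censoring in (QUANT_CENSORED, QUAL_CENSORED)
    return classify_censoring(
        value_present=record.value is not None and not below,
        below_lod=below,
        lod_present=record.lod is not None,
    )


def censoring_summary(
    db: pd.DataFrame, group_by: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Exact censoring counts and proportions per group.

    ``db`` is any record table with a ``censoring`` column.  Returns one row
    per group with n_total, the three state counts, n_quantitative
    (= n_total - n_qual_censored: observations carrying a measured value or a
    known LOD) and the state proportions.  Empty groups are simply absent.
    """
    if group_by:
        grouped = db.groupby(list(group_by), observed=True)
        keys_frames = [
            (dict(zip(group_by, key if isinstance(key, tuple) else (key,))), sub)
            for key, sub in grouped
        ]
    else:
        keys_frames = [({}, db)]

    rows = []
    for keys, sub in keys_frames:
        counts = sub["censoring"].value_counts()
        n_total = int(len(sub))
        if n_total == 0:
            continue
        n_unc = int(counts.get(UNCENSORED, 0))
        n_quant = int(counts.get(QUANT_CENSORED, 0))
        n_qual = int(counts.get(QUAL_CENSORED, 0))
        rows.append(
            {
                **keys,
                "n_total": n_total,
                "n_uncensored": n_unc,
                "n_quant_censored": n_quant,
                "n_qual_censored": n_qual,
                "n_quantitative": n_total - n_qual,
                "prop_uncensored": n_unc / n_total,
                "prop_quant_censored": n_quant / n_total,
                "prop_qual_censored": n_qual / n_total,
            }
        )
    return pd.DataFrame(rows)


def data_amount_summary(
    db: pd.DataFrame,
    keys: Sequence[str],
    include_sums: bool = True,
) -> pd.DataFrame:
    """Quantitative data amount per key combination.

    A data point counts as quantitative when it has a measured value or a
    known LOD; qualitatively censored observations are excluded because they
    carry no quantitative information.  ``include_sums=False`` additionally
    drops sum-of-compound rows, so the audit can be reported both ways.
    """
    sub = db[db["censoring"] != QUAL_CENSORED]
    if not include_sums and "is_sum" in sub.columns:
        sub = sub[~sub["is_sum"].astype(bool)]
    if sub.empty:
        return pd.DataFrame(columns=[*keys, "n"])
    out = (
        sub.groupby(list(keys), observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out
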