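"""Mother-offspring pairing, partition ratios, and structure-transfer relations.

The central statistic is the partition (maternal-transfer) ratio
R = log10(C_offspring / C_mother) for a compound measured in a mother tissue
and the paired offspring matrix.  On a lipid-normalized basis, R = 0 is the
equilibrium expectation for lipophilic compounds; |R| <= 1 marks a 10-fold
band around equilibrium.  PFAS, being amphiphilic, are analyzed on a
wet-weight basis by default, with lipid-normalized as the secondary view.

Ratios use uncensored observations only — censored values never enter ratios
or correlations, they are accounted for in the censoring audit instead.
Quartiles follow linear interpolation (numpy's default, type 7), stated here
so independent implementations can match exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import OFFSPRING_MATRICES, UNCENSORED

PAIRING_POLICIES = ("per_egg", "clutch_mean")

PAIR_COLUMNS = [
    "study_id",
    "species",
    "mother_id",
    "mother_tissue",
    "offspring_id",
    "offspring_matrix",
    "compound_id",
    "compound_class",
    "basis",
    "c_mother",
    "c_offspring",
    "censoring_mother",
    "censoring_offspring",
]


def _conc_column(basis: str) -> str:
    if basis == "lipid":
        return "conc_ng_g_lw"
    if basis == "wet":
        return "conc_ng_g_ww"
    raise ValueError(f"unknown analysis basis: {basis!r}")


def pair_mother_offspring(
    db: pd.DataFrame,
    policy: str = "per_egg",
    basis: str = "lipid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair offspring observations with their mother's tissue observations.

    ``db`` is a harmonized record table (one row per observation) with
    ``subject_role``, ``mother_id`` linkage, ``tissue``, ``compound_id``,
    ``censoring`` and the ng/g columns.  One pair is formed per
    (mother, offspring unit, compound, mother tissue, offspring matrix); both
    concentrations are on the declared ``basis``.

    Under ``clutch_mean`` the replicate eggs of a clutch are first collapsed
    to the geometric mean of their uncensored values (a clutch with no
    uncensored egg stays as a single censored pseudo-offspring so the pair is
    still counted by the audit).

    Returns (pairs, diagnostics); offspring whose mother_id matches no mother
    observation are reported, not paired.
    """
    if policy not in PAIRING_POLICIES:
        raise ValueError(f"unknown pairing policy: {policy!r}")
    conc = _conc_column(basis)

    mothers = db[db["subject_role"] == "mother"]
    offspring = db[db["subject_role"] == "offspring"]
    offspring = offspring[offspring["tissue"].isin(OFFSPRING_MATRICES)]

    mother_keys = set(
        zip(mothers["study_id"], mothers["mother_id"].astype(str))
    )

    diagnostics = []
    linked = []
    for _, row in offspring.iterrows():
        key = (row["study_id"], str(row["mother_id"]))
        if row["mother_id"] is None or key not in mother_keys:
            diagnostics.append(
                {
                    "study_id": row["study_id"],
                    "offspring_id": row["subject_id"],
                    "message": "offspring without a linked mother observation",
                }
            )
        else:
            linked.append(row)
    if linked:
        off = pd.DataFrame(linked)
    else:
        off = offspring.iloc[0:0]

    if policy == "clutch_mean" and not off.empty:
        off = _collapse_clutches(off, conc)

    rows = []
    if not off.empty:
        m = mothers[
            [
                "study_id",
                "species",
                "mother_id",
                "tissue",
                "compound_id",
                "compound_class",
                "censoring",
                conc,
            ]
        ].rename(columns={"tissue": "mother_tissue", "censoring": "censoring_mother", conc: "c_mother"})
        o = off[
            ["study_id", "mother_id", "subject_id", "tissue", "compound_id", "censoring", conc]
        ].rename(
            columns={
                "subject_id": "offspring_id",
                "tissue": "offspring_matrix",
                "censoring": "censoring_offspring",
                conc: "c_offspring",
            }
        )
        merged = o.merge(m, on=["study_id", "mother_id", "compound_id"], how="inner")
        for _, r in merged.iterrows():
            rows.append(
                {
                    "study_id": r["study_id"],
                    "species": r["species"],
                    "mother_id": r["mother_id"],
                    "mother_tissue": r["mother_tissue"],
                    "offspring_id": r["offspring_id"],
                    "offspring_matrix": r["offspring_matrix"],
                    "compound_id": r["compound_id"],
                    "compound_class": r["compound_class"],
                    "basis": basis,
                    "c_mother": r["c_mother"],
                    "c_offspring": r["c_offspring"],
                    "censoring_mother": r["censoring_mother"],
                    "censoring_offspring": r["censoring_offspring"],
                }
            )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs, pd.DataFrame(diagnostics, columns=["study_id", "offspring_id", "message"])


def _collapse_clutches(off: pd.DataFrame, conc: str) -> pd.DataFrame:
    """Geometric-mean collapse of replicate eggs per clutch and compound."""
    out = []
    keys = ["study_id", "mother_id", "tissue", "compound_id"]
    for key, sub in off.groupby(keys, observed=True, dropna=False):
        unc = sub[(sub["censoring"] == UNCENSORED) & (sub[conc] > 0)]
        rep = sub.iloc[0].copy()
        rep["subject_id"] = f"{key[1]}/clutch"
        if len(unc):
            rep[conc] = float(np.exp(np.mean(np.log(unc[conc].astype(float)))))
            rep["censoring"] = UNCENSORED
        else:
            rep[conc] = np.nan
            rep["censoring"] = sub["censoring"].iloc[0]
        out.append(rep)
    return pd.DataFrame(out)


# -- ratios ------------------------------------------------------------------

SKIP_CENSORED_MOTHER = "censored_mother"
SKIP_CENSORED_OFFSPRING = "censored_offspring"
SKIP_ZERO = "zero_concentration"
SKIP_MISSING = "missing_concentration"


def transfer_ratio_value(c_mother: float, c_offspring: float) -> float:
    """R = log10(c_offspring / c_mother) for positive concentrations."""
    if c_mother <= 0 or c_offspring <= 0:
        raise ValueError("transfer ratio requires strictly positive concentrations")
    return math.log10(c_offspring) - math.log10(c_mother)


def transfer_ratios(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute R for every eligible pair; ineligible pairs get a reason.

    Eligible: both sides uncensored with strictly positive concentrations.
    Returns (ratios, skipped); ratios carries all pair columns plus ``R``.
    """
    ok_rows, skipped = [], []
    for _, row in pairs.iterrows():
        reason = None
        if row["censoring_mother"] != UNCENSORED:
            reason = SKIP_CENSORED_MOTHER
        elif row["censoring_offspring"] != UNCENSORED:
            reason = SKIP_CENSORED_OFFSPRING
        elif pd.isna(row["c_mother"]) or pd.isna(row["c_offspring"]):
            reason = SKIP_MISSING
        elif row["c_mother"] <= 0 or row["c_offspring"] <= 0:
            reason = SKIP_ZERO
        if reason:
            skipped.append({**row.to_dict(), "reason": reason})
            continue
        d = row.to_dict()
        d["R"] = transfer_ratio_value(row["c_mother"], row["c_offspring"])
        ok_rows.append(d)
    ratios = pd.DataFrame(ok_rows, columns=PAIR_COLUMNS + ["R"])
    return ratios, pd.DataFrame(skipped, columns=PAIR_COLUMNS + ["reason"])


def equilibrium_band(r: float) -> str:
    """Band a ratio against the 10-fold envelope: |R| <= 1 is within (inclusive)."""
    if not math.isfinite(r):
        raise ValueError("equilibrium banding requires a finite ratio")
    if abs(r) <= 1.0:
        return "within_10fold"
    return "above" if r > 1.0 else "below"


def band_counts(ratios: pd.DataFrame, by: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Counts of ratios per equilibrium band, optionally per group."""
    df = ratios.copy()
    df["band"] = df["R"].map(equilibrium_band)
    keys = (list(by) if by else []) + ["band"]
    return df.groupby(keys, observed=True).size().rename("n").reset_index()


def ratio_summary(
    ratios: pd.DataFrame,
    by: Sequence[str] = ("species", "mother_tissue", "compound_class"),
) -> pd.DataFrame:
    """Boxplot-style summary per group: median, quartiles, 1.5*IQR whiskers.

    Quartiles use linear interpolation (type 7); whiskers extend 1.5 times the
    interquartile range beyond the quartiles, clamped to the observed extremes;
    points beyond the whiskers are counted as outliers.  Empty groups are
    omitted.
    """
    rows = []
    for key, sub in ratios.groupby(list(by), observed=True):
        x = sub["R"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = max(x.min(), q1 - 1.5 * iqr)
        hi = min(x.max(), q3 + 1.5 * iqr)
        keys = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rows.append(
            {
                **keys,
                "n": len(x),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(iqr),
                "whisker_low": float(lo),
                "whisker_high": float(hi),
                "n_outliers": int(((x < lo) | (x > hi)).sum()),
            }
        )
    return pd.DataFrame(rows)


# -- maternal tissue correlations -------------------------------------------


def tissue_correlations(
    mother_db: pd.DataFrame,
    min_pairs: int = 10,
    value_column: str = "conc_ng_g_lw",
) -> tuple[pd.DataFrame, dict]:
    """Correlate log10 concentrations between maternal tissues.

    For every tissue pair, co-measured observations are the (study, mother,
    compound) combinations with uncensored positive values in both tissues;
    pairs with fewer than ``min_pairs`` such observations are absent from the
    output.  Pearson correlations (on log10 values) are primary; Spearman is
    emitted alongside.  The summary reports median/min/max of the qualifying
    Pearson entries.
    """
    sub = mother_db[
        (mother_db["subject_role"] == "mother")
        & (mother_db["censoring"] == UNCENSORED)
        & (mother_db[value_column] > 0)
    ].copy()
    sub["log_conc"] = np.log10(sub[value_column].astype(float))
    wide = sub.pivot_table(
        index=["study_id", "subject_id", "compound_id"],
        columns="tissue",
        values="log_conc",
        aggfunc="mean",
    )
    tissues = sorted(wide.columns)
    rows = []
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1 :]:
            both = wide[[ta, tb]].dropna()
            if len(both) < min_pairs:
                continue
            a, b = both[ta].to_numpy(), both[tb].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                pearson = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else math.nan
                spearman = math.nan
            else:
                pearson = float(stats.pearsonr(a, b).statistic)
                spearman = float(stats.spearmanr(a, b).statistic)
            rows.append(
                {
                    "tissue_a": ta,
                    "tissue_b": tb,
                    "n": len(both),
                    "pearson": pearson,
                    "spearman": spearman,
                }
            )
    matrix = pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "n", "pearson", "spearman"])
    if len(matrix):
        vals = matrix["pearson"].dropna()
        summary = {
            "median": float(vals.median()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_pairs": int(len(matrix)),
        }
    else:
        summary = {"median": math.nan, "min": math.nan, "max": math.nan, "n_pairs": 0}
    return matrix, summary


# -- ratio vs lipophilicity --------------------------------------------------

LOW_N_THRESHOLD = 5


def ratio_vs_kow(
    ratios: pd.DataFrame,
    log_kow: Mapping[str, float],
    by: Sequence[str] = ("species", "mother_tissue", "compound_class"),
) -> pd.DataFrame:
    """Relate partition ratios to compound lipophilicity per group.

    For every group: least-squares slope/intercept of R on log10 Kow (with
    the slope's standard error), Spearman rank correlation, and n.  Pairs
    without an assigned log Kow are excluded.  Groups where every compound
    shares one log Kow have no defined slope and are flagged; groups with
    n < 5 are flagged low-n.
    """
    df = ratios.copy()
    df["log_kow"] = df["compound_id"].map(log_kow)
    df = df[df["log_kow"].notna() & np.isfinite(df["R"])]
    rows = []
    for key, sub in df.groupby(list(by), observed=True):
        keys = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        x = sub["log_kow"].to_numpy(dtype=float)
        y = sub["R"].to_numpy(dtype=float)
        n = len(sub)
        row = {
            **keys,
            "n": n,
            "low_n": n < LOW_N_THRESHOLD,
            "slope": math.nan,
            "intercept": math.nan,
            "slope_stderr": math.nan,
            "spearman": math.nan,
            "undefined_slope": False,
        }
        if len(np.unique(x)) < 2:
            row["undefined_slope"] = True
        else:
            fit = stats.linregress(x, y)
            row["slope"] = float(fit.slope)
            row["intercept"] = float(fit.intercept)
            row["slope_stderr"] = float(fit.stderr)
            row["spearman"] = float(stats.spearmanr(x, y).statistic)
        rows.append(row)
    return pd.DataFrame(rows)
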