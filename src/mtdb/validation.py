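"""Pre-registered validation study conditions for end-to-end checks.

These configurations exercise the whole pipeline (generate -> harmonize ->
pair -> ratio statistics / censoring audit) under conditions where the truth
is known in closed form.  They are defined once, here, so the test suite and
the acceptance script run the identical conditions:

* ``recovery_config`` — a single well-powered study for recovering the
  transfer offset alpha (via the median partition ratio) and the
  lipophilicity slope beta (via the ratio-vs-log Kow regression).  Egg noise
  sigma_e is the only noise source, so per-egg ratios are i.i.d.
  ``alpha + beta * log_kow + Normal(0, sigma_e)`` and standard regression
  errors apply.
* ``censoring_config`` — one tissue, one egg per mother, all noise off:
  every mother x compound cluster is fully concordant, so the censored
  fraction is an exact binomial over ``n_mothers * n_compounds`` independent
  clusters at success probability q_lod.
* ``banding_config`` — noiseless transfer with every compound's true offset
  |alpha + beta * log_kow| < 1, so every ratio must fall inside the 10-fold
  equilibrium band.
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    DEFAULT_COMPOUNDS,
    SyntheticCompound,
    SyntheticConfig,
    SyntheticStudy,
    SyntheticTissue,
)

#: Compound panel spanning log Kow ~ 4.5-7.6 (the range the real database covers).
PANEL = DEFAULT_COMPOUNDS


def _single_study(
    n_mothers: int, eggs_per_mother: int, species: str = "Malaclemys terrapin"
) -> SyntheticStudy:
    return SyntheticStudy(
        study_id="V1",
        species=species,
        n_mothers=n_mothers,
        eggs_per_mother=eggs_per_mother,
        mother_tissues=(SyntheticTissue("liver", 0.05),),
        offspring_matrix=SyntheticTissue("whole_egg", 0.08),
        unit="ng/g",
        basis="wet",
        pooling_prob=0.0,
    )


def recovery_config(
    seed: int,
    alpha: float = -0.5,
    beta: float = 0.0,
    sigma_e: float = 0.2,
    n_mothers: int = 200,
    eggs_per_mother: int = 2,
) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        studies=(_single_study(n_mothers, eggs_per_mother),),
        compounds=PANEL,
        mu_m=2.0,
        sigma_m=0.8,
        alpha=alpha,
        beta=beta,
        sigma_e=sigma_e,
        sigma_tissue=0.0,
        q_lod=0.0,
        p_qual=0.0,
    )


def censoring_config(
    seed: int, q_lod: float = 0.73, p_qual: float = 0.5, n_mothers: int = 150
) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        studies=(_single_study(n_mothers, eggs_per_mother=1),),
        compounds=PANEL,
        mu_m=2.0,
        sigma_m=0.8,
        alpha=0.0,
        beta=0.0,
        sigma_e=0.0,
        sigma_tissue=0.0,
        q_lod=q_lod,
        p_qual=p_qual,
    )


def censoring_n_independent(config: SyntheticConfig) -> int:
    """Independent censoring clusters: with all noise off, every record of a
    mother x compound combination is identical, so clusters are the unit."""
    return sum(s.n_mothers for s in config.studies) * len(config.compounds)


def binomial_99_bound(p: float, n: int) -> float:
    """Half-width of the 99% normal-approximation binomial band for p-hat."""
    from scipy import stats

    return float(stats.norm.ppf(0.995)) * np.sqrt(p * (1 - p) / n)


def _pipeline_ratios(config: SyntheticConfig):
    """generate -> harmonize -> pair -> ratios, as the pipeline would run them."""
    from .harmonize import harmonize_table
    from .records import harmonized_to_frame
    from .simulate import generate
    from .transfer import pair_mother_offspring, transfer_ratios

    ds = generate(config)
    harmonized, _ = harmonize_table(ds.records, ds.lipid_table, ds.water_table)
    db = harmonized_to_frame(harmonized)
    pairs, _ = pair_mother_offspring(db, policy="per_egg", basis="lipid")
    ratios, _ = transfer_ratios(pairs)
    return ratios, ds


def measure_recovery(config: SyntheticConfig) -> dict[str, float]:
    """Median partition ratio and the fitted ratio-vs-log Kow slope."""
    from .simulate import kow_map
    from .transfer import ratio_vs_kow

    ratios, ds = _pipeline_ratios(config)
    ratios = ratios.assign(group="all")
    fit = ratio_vs_kow(ratios, kow_map(config), by=("group",)).iloc[0]
    return {
        "median_ratio": float(ratios["R"].median()),
        "slope": float(fit["slope"]),
        "slope_stderr": float(fit["slope_stderr"]),
        "n_ratios": int(len(ratios)),
    }


def measure_censoring(config: SyntheticConfig) -> dict[str, float]:
    """Audit censoring proportions on the harmonized synthetic database."""
    from .censoring import censoring_summary
    from .harmonize import harmonize_table
    from .records import harmonized_to_frame
    from .simulate import generate

    ds = generate(config)
    harmonized, _ = harmonize_table(ds.records, ds.lipid_table, ds.water_table)
    db = harmonized_to_frame(harmonized)
    row = censoring_summary(db).iloc[0]
    return {
        "censored_fraction": float(
            row["prop_quant_censored"] + row["prop_qual_censored"]
        ),
        "qual_share": float(row["prop_qual_censored"]),
        "n_records": int(row["n_total"]),
    }


def measure_banding(config: SyntheticConfig) -> dict[str, float]:
    """Share of partition ratios inside the 10-fold equilibrium band."""
    from .transfer import equilibrium_band

    ratios, _ = _pipeline_ratios(config)
    bands = ratios["R"].map(equilibrium_band)
    return {
        "fraction_within_10fold": float((bands == "within_10fold").mean()),
        "n_ratios": int(len(ratios)),
    }


def banding_config(seed: int) -> SyntheticConfig:
    # |alpha + beta * log_kow| stays well inside (-1, 1) over the panel
    return SyntheticConfig(
        seed=seed,
        studies=(_single_study(n_mothers=20, eggs_per_mother=2),),
        compounds=PANEL,
        mu_m=2.0,
        sigma_m=0.8,
        alpha=-0.3,
        beta=0.05,
        sigma_e=0.0,
        sigma_tissue=0.0,
        q_lod=0.0,
        p_qual=0.0,
    )
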