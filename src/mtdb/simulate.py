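"""Synthetic multi-study mother-offspring datasets with known ground truth.

The generator emulates the structure of published maternal-transfer data:
several studies, each with its own species, maternal tissues (with true lipid
fractions), offspring matrix, reporting unit and measurement basis; lognormal
lipid-normalized mother concentrations; a Kow-dependent transfer model

    log10 C_offspring = log10 C_mother + alpha + beta * log10 Kow + eps,
    eps ~ Normal(0, sigma_e);

three-state censoring driven by a per-compound LOD placed at a quantile of
the mother concentration distribution, with a fraction of censored records
withholding the LOD (qualitative censoring); and occasional clutches reported
only as geometric means.  Records are expressed in each study's declared unit
and basis, so harmonization must exactly undo the encoding; every latent
value is kept in a truth table.

All randomness flows through one numpy Generator seeded from the config, so a
fixed seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import unit_factor
from .records import (
    QUAL_CENSORED,
    QUANT_CENSORED,
    UNCENSORED,
    LipidEntry,
    StudyRecord,
    WaterEntry,
    records_to_frame,
)


@dataclass(frozen=True)
class SyntheticCompound:
    compound_id: str
    compound_class: str
    log_kow: float


@dataclass(frozen=True)
class SyntheticTissue:
    name: str
    lipid_fraction: float


@dataclass(frozen=True)
class SyntheticStudy:
    study_id: str
    species: str
    n_mothers: int
    eggs_per_mother: int
    mother_tissues: tuple[SyntheticTissue, ...]
    offspring_matrix: SyntheticTissue
    unit: str = "ng/g"
    basis: str = "wet"  # wet | dry | lipid
    water_fraction: float = 0.0  # used when basis == "dry"
    pooling_prob: float = 0.0  # P(clutch reported as a geometric mean)
    compounds: Optional[tuple[str, ...]] = None  # None -> all config compounds


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the simulated multi-study dataset.

    Concentrations are modelled on the lipid-normalized (ng/g lipid) scale:
    ``log10 C_mother ~ Normal(mu_m, sigma_m)`` per mother and compound, shared
    across her tissues up to ``Normal(0, sigma_tissue)`` tissue scatter; the
    offspring value adds ``alpha + beta * log_kow`` and ``Normal(0, sigma_e)``
    egg noise.  ``q_lod`` places every compound's LOD at that quantile of the
    mother concentration distribution (0 disables censoring, 1 censors
    everything); ``p_qual`` is the share of censored records whose LOD is
    withheld.
    """

    seed: int
    studies: tuple[SyntheticStudy, ...]
    compounds: tuple[SyntheticCompound, ...]
    mu_m: float = 2.0
    sigma_m: float = 0.8
    alpha: float = -0.2
    beta: float = 0.0
    sigma_e: float = 0.25
    sigma_tissue: float = 0.05
    q_lod: float = 0.0
    p_qual: float = 0.5

    def validate(self) -> None:
        if not self.studies:
            raise ValueError("config needs at least one study")
        if not self.compounds:
            raise ValueError("config needs at least one compound")
        if min(self.sigma_m, self.sigma_e, self.sigma_tissue) < 0:
            raise ValueError("sigmas must be non-negative")
        if not (0.0 <= self.q_lod <= 1.0):
            raise ValueError("q_lod must lie in [0, 1]")
        if not (0.0 <= self.p_qual <= 1.0):
            raise ValueError("p_qual must lie in [0, 1]")
        ids = {c.compound_id for c in self.compounds}
        for s in self.studies:
            if s.n_mothers < 1 or s.eggs_per_mother < 1:
                raise ValueError(f"{s.study_id}: need >= 1 mother and egg")
            if not (0.0 <= s.pooling_prob <= 1.0):
                raise ValueError(f"{s.study_id}: pooling_prob outside [0, 1]")
            if s.basis == "dry" and not (0.0 <= s.water_fraction < 1.0):
                raise ValueError(f"{s.study_id}: dry basis needs water_fraction in [0, 1)")
            if s.basis not in ("wet", "dry", "lipid"):
                raise ValueError(f"{s.study_id}: unknown basis {s.basis!r}")
            unit_factor(s.unit)  # raises on unsupported unit
            for t in (*s.mother_tissues, s.offspring_matrix):
                if not (0.0 < t.lipid_fraction <= 1.0):
                    raise ValueError(f"{s.study_id}/{t.name}: bad lipid fraction")
            if s.compounds is not None and not set(s.compounds) <= ids:
                raise ValueError(f"{s.study_id}: unknown compound in study subset")

    def study_compounds(self, study: SyntheticStudy) -> tuple[SyntheticCompound, ...]:
        if study.compounds is None:
            return self.compounds
        wanted = set(study.compounds)
        return tuple(c for c in self.compounds if c.compound_id in wanted)


@dataclass
class SyntheticDataset:
    records: list[StudyRecord]
    truth: pd.DataFrame
    lipid_table: list[LipidEntry]
    water_table: list[WaterEntry]
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the delimited-text files the ingestion layer reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out / "study_records.csv",
            "truth": out / "truth.csv",
            "lipid_table": out / "lipid_table.csv",
            "water_table": out / "water_table.csv",
        }
        records_to_frame(self.records).to_csv(paths["records"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        pd.DataFrame(
            [
                {
                    "species": e.species,
                    "tissue": e.tissue,
                    "lipid_fraction": e.lipid_fraction,
                    "source": e.source,
                    "reference": e.reference,
                }
                for e in self.lipid_table
            ]
        ).to_csv(paths["lipid_table"], index=False)
        pd.DataFrame(
            [
                {
                    "species": e.species,
                    "tissue": e.tissue,
                    "water_fraction": e.water_fraction,
                    "reference": e.reference,
                }
                for e in self.water_table
            ]
        ).to_csv(paths["water_table"], index=False)
        return paths


#: Identity column map for generated study tables.
IDENTITY_COLUMN_MAP = {
    "study_id": "study_id",
    "species": "species",
    "subject_role": "subject_role",
    "subject_id": "subject_id",
    "mother_id": "mother_id",
    "tissue": "tissue",
    "compound": "compound_raw",
    "compound_class": "compound_class",
    "value": "value",
    "unit": "unit",
    "basis": "basis",
    "censored": "censoring_flag",
    "lod": "lod",
    "n_pooled": "n_pooled",
    "aggregation": "aggregation",
    "is_sum": "is_sum",
    "is_coelution": "is_coelution",
    "members": "members",
    "lipid_fraction_reported": "lipid_fraction_reported",
    "out_of_calibration": "out_of_calibration",
}


def _encode(lw: float, study: SyntheticStudy, tissue: SyntheticTissue) -> float:
    """Express a lipid-normalized ng/g value in the study's declared unit/basis."""
    if study.basis == "lipid":
        basis_value = Fraction(lw)
    else:
        ww = Fraction(lw) * Fraction(tissue.lipid_fraction)
        if study.basis == "dry":
            basis_value = ww / (1 - Fraction(study.water_fraction))
        else:
            basis_value = ww
    return float(basis_value / unit_factor(study.unit))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Sample a full multi-study dataset plus its ground-truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Per-compound LOD on the log10 lipid-normalized scale.
    if config.q_lod <= 0.0:
        lod_log10 = -math.inf
    elif config.q_lod >= 1.0:
        lod_log10 = math.inf
    else:
        lod_log10 = config.mu_m + config.sigma_m * float(stats.norm.ppf(config.q_lod))

    records: list[StudyRecord] = []
    truth_rows: list[dict] = []
    lipid_entries: dict[tuple[str, str], LipidEntry] = {}
    water_entries: dict[tuple[str, str], WaterEntry] = {}

    def emit(
        study: SyntheticStudy,
        role: str,
        subject_id: str,
        mother_id: str,
        tissue: SyntheticTissue,
        compound: SyntheticCompound,
        log10_lw: float,
        aggregation: str = "individual",
        n_pooled: int = 1,
    ) -> None:
        true_lw = 10.0 ** log10_lw
        censored = log10_lw < lod_log10
        qual = bool(censored and rng.random() < config.p_qual)
        if censored:
            if not math.isfinite(lod_log10):
                qual = True  # an unbounded LOD carries no quantitative information
            censoring = QUAL_CENSORED if qual else QUANT_CENSORED
            value = None
            lod = None if qual else _encode(10.0 ** lod_log10, study, tissue)
        else:
            censoring = UNCENSORED
            value = _encode(true_lw, study, tissue)
            lod = None
        records.append(
            StudyRecord(
                study_id=study.study_id,
                species=study.species,
                subject_role=role,
                subject_id=subject_id,
                mother_id=mother_id,
                tissue=tissue.name,
                compound_raw=compound.compound_id,
                compound_id=compound.compound_id,
                compound_resolved=True,
                compound_class=compound.compound_class,
                value=value,
                unit=study.unit,
                basis=study.basis,
                censoring=censoring,
                lod=lod,
                aggregation=aggregation,
                n_pooled=n_pooled,
            )
        )
        truth_rows.append(
            {
                "study_id": study.study_id,
                "species": study.species,
                "subject_role": role,
                "subject_id": subject_id,
                "mother_id": mother_id,
                "tissue": tissue.name,
                "compound_id": compound.compound_id,
                "compound_class": compound.compound_class,
                "log_kow": compound.log_kow,
                "true_conc_ng_g_lw": true_lw,
                "lod_ng_g_lw": 10.0 ** lod_log10 if math.isfinite(lod_log10) else None,
                "censored": censored,
                "qual_censored": qual,
            }
        )

    for study in config.studies:
        for t in (*study.mother_tissues, study.offspring_matrix):
            lipid_entries.setdefault(
                (study.species, t.name),
                LipidEntry(
                    species=study.species,
                    tissue=t.name,
                    lipid_fraction=t.lipid_fraction,
                    source="same_species_literature",
                    reference="synthetic ground truth",
                ),
            )
            if study.basis == "dry":
                water_entries.setdefault(
                    (study.species, t.name),
                    WaterEntry(
                        species=study.species,
                        tissue=t.name,
                        water_fraction=study.water_fraction,
                        reference="synthetic ground truth",
                    ),
                )
        compounds = config.study_compounds(study)
        for i in range(study.n_mothers):
            mother_id = f"{study.study_id}_M{i + 1}"
            pooled = bool(rng.random() < study.pooling_prob)
            for compound in compounds:
                u = rng.normal(config.mu_m, config.sigma_m)
                for tissue in study.mother_tissues:
                    scatter = (
                        rng.normal(0.0, config.sigma_tissue)
                        if config.sigma_tissue > 0
                        else 0.0
                    )
                    emit(study, "mother", mother_id, mother_id, tissue, compound, u + scatter)
                shift = config.alpha + config.beta * compound.log_kow
                egg_values = [
                    u
                    + shift
                    + (rng.normal(0.0, config.sigma_e) if config.sigma_e > 0 else 0.0)
                    for _ in range(study.eggs_per_mother)
                ]
                if pooled:
                    emit(
                        study,
                        "offspring",
                        f"{mother_id}_pool",
                        mother_id,
                        study.offspring_matrix,
                        compound,
                        float(np.mean(egg_values)),  # geometric mean on the log scale
                        aggregation="geometric_mean",
                        n_pooled=study.eggs_per_mother,
                    )
                else:
                    for e, log_lw in enumerate(egg_values):
                        emit(
                            study,
                            "offspring",
                            f"{mother_id}_E{e + 1}",
                            mother_id,
                            study.offspring_matrix,
                            compound,
                            log_lw,
                        )

    truth = pd.DataFrame(truth_rows)
    truth.attrs["alpha"] = config.alpha
    truth.attrs["beta"] = config.beta
    return SyntheticDataset(
        records=records,
        truth=truth,
        lipid_table=sorted(lipid_entries.values(), key=lambda e: (e.species, e.tissue)),
        water_table=sorted(water_entries.values(), key=lambda e: (e.species, e.tissue)),
        config=config,
    )


# -- analytic expectations ---------------------------------------------------


def expected_statistics(config: SyntheticConfig) -> dict[str, float]:
    """Closed-form expectations for recovery checks against the pipeline.

    ``expected_median_ratio``: alpha + beta * mean(log Kow) over the config's
    compounds (the egg noise is symmetric about the shifted mother value).

    ``expected_censored_fraction``: record-count-weighted normal-CDF
    probability of falling below the LOD, accounting for the different
    marginal variances of mother-tissue records (sigma_m, sigma_tissue),
    per-egg records (sigma_m, sigma_e) and pooled clutch records (egg noise
    averaged over the clutch), and for each study's expected pooled/unpooled
    record mix.  ``expected_qual_share`` multiplies by p_qual.
    """
    config.validate()
    kows = [c.log_kow for c in config.compounds]
    expected_median = config.alpha + config.beta * float(np.mean(kows))

    if config.q_lod <= 0.0:
        return {
            "expected_median_ratio": expected_median,
            "expected_censored_fraction": 0.0,
            "expected_qual_share": 0.0,
        }
    if config.q_lod >= 1.0:
        return {
            "expected_median_ratio": expected_median,
            "expected_censored_fraction": 1.0,
            "expected_qual_share": config.p_qual,
        }

    z = float(stats.norm.ppf(config.q_lod))
    lod_log10 = config.mu_m + config.sigma_m * z
    sd_mother = math.hypot(config.sigma_m, config.sigma_tissue)
    weighted_p = 0.0
    weight = 0.0
    for study in config.studies:
        compounds = config.study_compounds(study)
        n_tissue_records = study.n_mothers * len(study.mother_tissues)
        n_egg = study.n_mothers * study.eggs_per_mother * (1 - study.pooling_prob)
        n_pool = study.n_mothers * study.pooling_prob
        sd_egg = math.hypot(config.sigma_m, config.sigma_e)
        sd_pool = math.hypot(
            config.sigma_m, config.sigma_e / math.sqrt(study.eggs_per_mother)
        )
        for compound in compounds:
            shift = config.alpha + config.beta * compound.log_kow
            p_mother = float(
                stats.norm.cdf((lod_log10 - config.mu_m) / sd_mother)
            ) if sd_mother > 0 else float(lod_log10 > config.mu_m)
            mean_off = config.mu_m + shift
            p_egg = (
                float(stats.norm.cdf((lod_log10 - mean_off) / sd_egg))
                if sd_egg > 0
                else float(lod_log10 > mean_off)
            )
            p_pool = (
                float(stats.norm.cdf((lod_log10 - mean_off) / sd_pool))
                if sd_pool > 0
                else float(lod_log10 > mean_off)
            )
            weighted_p += (
                n_tissue_records * p_mother + n_egg * p_egg + n_pool * p_pool
            )
            weight += n_tissue_records + n_egg + n_pool
    p_censored = weighted_p / weight
    return {
        "expected_median_ratio": expected_median,
        "expected_censored_fraction": p_censored,
        "expected_qual_share": p_censored * config.p_qual,
    }


def property_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Property table (chemprops layout) holding the generator's true log Kow.

    The true values are exposed as model estimates (``log_kow_estimated``)
    with no experimental column filled, matching the common case where most
    descriptors come from an estimation model.
    """
    frame = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in config.compounds],
            "log_kow_experimental": [math.nan] * len(config.compounds),
            "log_kow_estimated": [c.log_kow for c in config.compounds],
        }
    )
    return frame.set_index("compound_id")


def kow_map(config: SyntheticConfig) -> dict[str, float]:
    return {c.compound_id: c.log_kow for c in config.compounds}


# -- default fixture ---------------------------------------------------------

DEFAULT_COMPOUNDS: tuple[SyntheticCompound, ...] = (
    SyntheticCompound("PCB28", "PCB", 5.67),
    SyntheticCompound("PCB52", "PCB", 5.84),
    SyntheticCompound("PCB101", "PCB", 6.38),
    SyntheticCompound("PCB118", "PCB", 6.74),
    SyntheticCompound("PCB138", "PCB", 6.83),
    SyntheticCompound("PCB153", "PCB", 6.92),
    SyntheticCompound("PCB180", "PCB", 7.36),
    SyntheticCompound("p,p'-DDE", "OCP", 6.51),
    SyntheticCompound("p,p'-DDT", "OCP", 6.91),
    SyntheticCompound("p,p'-DDD", "OCP", 6.02),
    SyntheticCompound("dieldrin", "OCP", 5.40),
    SyntheticCompound("HCB", "OCP", 5.73),
    SyntheticCompound("trans-nonachlor", "OCP", 6.35),
    SyntheticCompound("BDE47", "HFR_BFR", 6.81),
    SyntheticCompound("BDE99", "HFR_BFR", 7.32),
    SyntheticCompound("PFOS", "PFAS", 4.49),
    SyntheticCompound("PFOA", "PFAS", 4.81),
    SyntheticCompound("benzo[a]pyrene", "PAH", 6.13),
    SyntheticCompound("pyrene", "PAH", 4.88),
    SyntheticCompound("DEHP", "phthalate", 7.60),
)

_LEGACY = tuple(
    c.compound_id for c in DEFAULT_COMPOUNDS if c.compound_class in ("PCB", "OCP", "HFR_BFR")
)


def default_config(seed: int) -> SyntheticConfig:
    """Default fixture mirroring the heterogeneity of the real database.

    Two data-rich flagship studies with several maternal tissues, one
    dry-weight-basis study, and three small whole-egg-only studies; mixed
    reporting units; roughly three-quarters of records censored, half of
    those qualitatively.
    """
    studies = (
        SyntheticStudy(
            study_id="S1_terrapin",
            species="Malaclemys terrapin",
            n_mothers=12,
            eggs_per_mother=3,
            mother_tissues=(
                SyntheticTissue("fat", 0.60),
                SyntheticTissue("liver", 0.04),
                SyntheticTissue("whole_blood", 0.003),
                SyntheticTissue("muscle", 0.01),
            ),
            offspring_matrix=SyntheticTissue("whole_egg", 0.08),
            unit="ng/g",
            basis="wet",
            pooling_prob=0.2,
            compounds=_LEGACY,
        ),
        SyntheticStudy(
            study_id="S2_chinensis",
            species="Enhydris chinensis",
            n_mothers=10,
            eggs_per_mother=4,
            mother_tissues=(
                SyntheticTissue("liver", 0.05),
                SyntheticTissue("muscle", 0.012),
                SyntheticTissue("kidney", 0.03),
                SyntheticTissue("skin", 0.02),
                SyntheticTissue("fat", 0.55),
                SyntheticTissue("whole_blood", 0.004),
            ),
            offspring_matrix=SyntheticTissue("whole_egg", 0.10),
            unit="µg/kg",
            basis="wet",
            pooling_prob=0.3,
        ),
        SyntheticStudy(
            study_id="S3_mydas",
            species="Chelonia mydas",
            n_mothers=8,
            eggs_per_mother=2,
            mother_tissues=(SyntheticTissue("plasma", 0.005),),
            offspring_matrix=SyntheticTissue("whole_egg", 0.07),
            unit="µg/g",
            basis="dry",
            water_fraction=0.667,
            compounds=("p,p'-DDE", "p,p'-DDT", "dieldrin", "HCB"),
        ),
        SyntheticStudy(
            study_id="S4_caretta",
            species="Caretta caretta",
            n_mothers=5,
            eggs_per_mother=2,
            mother_tissues=(SyntheticTissue("whole_blood", 0.004),),
            offspring_matrix=SyntheticTissue("yolk", 0.22),
            unit="ppb",
            basis="wet",
            pooling_prob=0.5,
            compounds=("PCB138", "PCB153", "PCB180", "p,p'-DDE"),
        ),
        SyntheticStudy(
            study_id="S5_sipedon",
            species="Nerodia sipedon",
            n_mothers=4,
            eggs_per_mother=3,
            mother_tissues=(SyntheticTissue("liver", 0.05),),
            offspring_matrix=SyntheticTissue("whole_egg", 0.09),
            unit="pg/g",
            basis="wet",
            compounds=("PCB101", "PCB118", "PCB153"),
        ),
        SyntheticStudy(
            study_id="S6_coriacea",
            species="Dermochelys coriacea",
            n_mothers=4,
            eggs_per_mother=2,
            mother_tissues=(SyntheticTissue("whole_blood", 0.004),),
            offspring_matrix=SyntheticTissue("whole_egg", 0.12),
            unit="mg/kg",
            basis="wet",
            compounds=("PCB153", "p,p'-DDE", "PFOS"),
        ),
    )
    return SyntheticConfig(
        seed=seed,
        studies=studies,
        compounds=DEFAULT_COMPOUNDS,
        mu_m=2.0,
        sigma_m=0.8,
        alpha=-0.2,
        beta=0.0,
        sigma_e=0.25,
        sigma_tissue=0.05,
        q_lod=0.73,
        p_qual=0.5,
    )
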