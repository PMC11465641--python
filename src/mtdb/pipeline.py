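"""Pipeline orchestration: build, audit and analyze runs over a configuration.

A :class:`PipelineConfig` names the input tables (study records, lipid and
water lookups, molecular-property and override tables), the analysis options
(pairing policy, minimum co-measured observations for tissue correlations,
the PFAS wet-weight switch) and the output directory.  Every emitted table
starts with a comment line carrying the configuration hash and seed, so any
output file can be traced to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import censoring as censoring_mod
from . import chemprops, harmonize, ingest, transfer
from .records import QUAL_CENSORED, harmonized_to_frame
from .simulate import IDENTITY_COLUMN_MAP


@dataclass
class PipelineConfig:
    study_table: str
    lipid_table: str
    output_dir: str
    water_table: Optional[str] = None
    property_table: Optional[str] = None
    override_table: Optional[str] = None
    synonym_table: Optional[str] = None
    relatedness_table: Optional[str] = None
    column_map: Mapping[str, str] = field(default_factory=lambda: dict(IDENTITY_COLUMN_MAP))
    pairing_policy: str = "per_egg"
    min_pairs: int = 10
    pfas_wet_basis: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        required = [self.study_table, self.lipid_table]
        optional = [
            self.water_table,
            self.property_table,
            self.override_table,
            self.synonym_table,
            self.relatedness_table,
        ]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    """CSV with a provenance comment line (# mtdb config=<hash> seed=<seed>)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# mtdb config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_build(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """ingest -> canonicalize -> screen -> harmonize (-> annotate properties).

    Writes the harmonized database, the exclusion report and the row/record
    diagnostics; every dropped record appears in exactly one report.
    """
    config.validate_paths()
    out = Path(config.output_dir)

    synonyms = ingest.load_synonym_table(config.synonym_table)
    records, row_diags = ingest.read_study_table(config.study_table, config.column_map)
    records = ingest.canonicalize_records(records, synonyms)
    kept, excluded = ingest.apply_exclusion_rules(records)

    lipid_table = harmonize.load_lipid_table(config.lipid_table)
    water_table = (
        harmonize.load_water_table(config.water_table) if config.water_table else ()
    )
    relatedness = (
        harmonize.load_relatedness_map(config.relatedness_table)
        if config.relatedness_table
        else harmonize.default_relatedness_map()
    )
    harmonized, h_diags = harmonize.harmonize_table(
        kept, lipid_table, water_table, relatedness
    )

    db = harmonized_to_frame(harmonized)
    exclusion_report = pd.DataFrame(
        [
            {
                "study_id": e.record.study_id,
                "subject_id": e.record.subject_id,
                "tissue": e.record.tissue,
                "compound": e.record.compound_raw,
                "reason": e.reason,
            }
            for e in excluded
        ],
        columns=["study_id", "subject_id", "tissue", "compound", "reason"],
    )
    diagnostics = pd.DataFrame(
        [{"row": d.row, "field": d.field, "message": d.message} for d in row_diags + h_diags],
        columns=["row", "field", "message"],
    )

    tables = {"harmonized": db, "excluded": exclusion_report, "diagnostics": diagnostics}

    if config.property_table:
        props_table = chemprops.load_property_table(config.property_table)
        overrides = (
            chemprops.load_override_table(config.override_table)
            if config.override_table
            else None
        )
        annotated = {}
        for r in kept:
            key = r.compound_id or r.compound_raw
            if key not in annotated:
                annotated[key] = chemprops.annotate_record(r, props_table, overrides)
        prop_rows = pd.DataFrame(
            [
                {"compound_id": cid, **{d: p.descriptor(d) for d in chemprops.DESCRIPTORS},
                 "kow_provenance": p.kow_provenance}
                for cid, p in sorted(annotated.items())
            ]
        )
        tables["properties"] = prop_rows

    for name, frame in tables.items():
        write_table(frame, out / f"{name}.csv", config)
    return tables


def run_audit(config: PipelineConfig, db: Optional[pd.DataFrame] = None) -> dict[str, pd.DataFrame]:
    """Censoring typology and data-amount tables over the harmonized database."""
    out = Path(config.output_dir)
    if db is None:
        db = read_table(out / "harmonized.csv")
    tables = {
        "censoring_by_study": censoring_mod.censoring_summary(db, ["study_id", "species"]),
        "censoring_overall": censoring_mod.censoring_summary(db),
        "data_amount_species_class": censoring_mod.data_amount_summary(
            db[db["subject_role"] == "offspring"],
            ["species", "compound_class", "tissue"],
        ),
        "data_amount_mother_tissue": censoring_mod.data_amount_summary(
            db[db["subject_role"] == "mother"], ["species", "tissue"]
        ),
        "data_amount_no_sums": censoring_mod.data_amount_summary(
            db, ["species", "compound_class"], include_sums=False
        ),
    }
    for name, frame in tables.items():
        write_table(frame, out / f"{name}.csv", config)
    return tables


def run_analyze(config: PipelineConfig, db: Optional[pd.DataFrame] = None) -> dict[str, pd.DataFrame]:
    """Pairing, partition ratios, equilibrium banding, summaries, correlations
    and ratio-vs-lipophilicity trends; PFAS additionally on wet weight."""
    out = Path(config.output_dir)
    if db is None:
        db = read_table(out / "harmonized.csv")

    pairs, pair_diags = transfer.pair_mother_offspring(
        db, policy=config.pairing_policy, basis="lipid"
    )
    ratios, skipped = transfer.transfer_ratios(pairs)
    tables = {
        "pairs": pairs,
        "pair_diagnostics": pair_diags,
        "ratios": ratios,
        "ratios_skipped": skipped,
        "band_counts": transfer.band_counts(ratios, by=["compound_class"]),
        "ratio_summary": transfer.ratio_summary(ratios),
        "tissue_correlations": transfer.tissue_correlations(db, config.min_pairs)[0],
    }

    kow = {}
    if config.property_table:
        props = chemprops.load_property_table(config.property_table)
        overrides = (
            chemprops.load_override_table(config.override_table)
            if config.override_table
            else None
        )
        for cid in ratios["compound_id"].dropna().unique():
            p = chemprops.attach_properties(cid, props, overrides)
            if p.log_kow is not None:
                kow[cid] = p.log_kow
    if kow:
        tables["ratio_vs_kow"] = transfer.ratio_vs_kow(ratios, kow)

    if config.pfas_wet_basis:
        pfas = db[db["compound_class"] == "PFAS"]
        if len(pfas):
            pfas_pairs, _ = transfer.pair_mother_offspring(
                pfas, policy=config.pairing_policy, basis="wet"
            )
            pfas_ratios, _ = transfer.transfer_ratios(pfas_pairs)
            tables["pfas_wet_ratios"] = pfas_ratios
            tables["pfas_wet_band_counts"] = transfer.band_counts(pfas_ratios)

    for name, frame in tables.items():
        write_table(frame, out / f"{name}.csv", config)
    return tables
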