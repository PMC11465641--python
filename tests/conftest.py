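import dataclasses

import pandas as pd
import pytest

from mtdb.harmonize import harmonize_table
from mtdb.ingest import load_synonym_table
from mtdb.records import harmonized_to_frame
from mtdb.simulate import default_config, generate


@pytest.fixture(scope="session")
def synonyms():
    return load_synonym_table()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic fixture (seed fixed for the whole suite)."""
    return generate(default_config(123))


@pytest.fixture(scope="session")
def harmonized_default(default_dataset):
    """Default fixture pushed through harmonization; returns (records, frame)."""
    ds = default_dataset
    harmonized, _ = harmonize_table(ds.records, ds.lipid_table, ds.water_table)
    return harmonized, harmonized_to_frame(harmonized)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Degenerate generator: no noise, no censoring, pure alpha offset."""
    cfg = dataclasses.replace(
        default_config(7),
        alpha=-0.5,
        beta=0.0,
        sigma_e=0.0,
        sigma_tissue=0.0,
        q_lod=0.0,
    )
    return generate(cfg)


@pytest.fixture()
def property_table():
    """Tiny descriptor table with experimental/estimated Kow columns."""
    frame = pd.DataFrame(
        [
            # cid, exp, est, mw, cplx, heavy, don, acc, tpsa, charge, rot
            ("PCB82", None, 6.1, 326.43, 316.0, 22, 0, 0, 0.0, 0, 1),
            ("PCB151", None, 6.8, 360.88, 332.0, 23, 0, 0, 0.0, 0, 1),
            ("PCB153", 6.92, 7.75, 360.88, 351.0, 24, 0, 0, 0.0, 0, 1),
            ("congA", 6.1, 6.4, 360.88, 300.0, 24, 0, 0, 0.0, 0, 1),
            ("congB", None, 6.1, 360.88, 300.0, 24, 0, 0, 0.0, 0, 1),
            ("congC", None, 6.1, 360.88, 300.0, 24, 0, 0, 0.0, 0, 1),
        ],
        columns=[
            "compound_id",
            "log_kow_experimental",
            "log_kow_estimated",
            "molecular_weight",
            "complexity",
            "heavy_atom_count",
            "h_bond_donors",
            "h_bond_acceptors",
            "tpsa",
            "formal_charge",
            "rotatable_bonds",
        ],
    )
    return frame.set_index("compound_id")


@pytest.fixture()
def override_table():
    return pd.DataFrame(
        [
            {"compound_key": "CP-C10", "descriptor": "log_kow", "value": 6.2,
             "reference": "chain-length model"},
            {"compound_key": "PCB151+PCB82", "descriptor": "log_kow", "value": 6.58,
             "reference": "experimental, combined peak"},
        ]
    )
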