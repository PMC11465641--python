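#!/usr/bin/env python
"""Audit censoring typology and data amounts in the harmonized database.

Reports how much of the database carries quantitative information: the
uncensored / quantitatively censored / qualitatively censored split overall
and per study, and the data-amount tables per species, compound class and
tissue (qualitatively censored rows excluded, since they carry no
quantitative information).  Outputs land in results/db/.
"""

import argparse
from pathlib import Path

from mtdb.pipeline import run_audit

import importlib.util

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location("build_step", ROOT / "analysis" / "02_build.py")
_build = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_build)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=123)
    args = parser.parse_args()

    tables = run_audit(_build.build_config(args.seed))
    overall = tables["censoring_overall"].iloc[0]
    print(
        f"{int(overall['n_total'])} records: "
        f"{100 * overall['prop_uncensored']:.1f}% uncensored, "
        f"{100 * overall['prop_quant_censored']:.1f}% quantitatively censored, "
        f"{100 * overall['prop_qual_censored']:.1f}% qualitatively censored"
    )
    print(f"{int(overall['n_quantitative'])} records carry quantitative information")
    per_study = tables["censoring_by_study"]
    worst = per_study.loc[per_study["prop_qual_censored"].idxmax()]
    print(
        f"most qualitative censoring: {worst['study_id']} "
        f"({100 * worst['prop_qual_censored']:.1f}%)"
    )
    print(f"tables written to {ROOT / 'results' / 'db'}")


if __name__ == "__main__":
    main()
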