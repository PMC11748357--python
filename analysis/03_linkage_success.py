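#!/usr/bin/env python
"""Evaluate linkage success: rates by tier and stratum, completeness, concordance.

Reads results/data/ and results/linkage/, profiles every state-year stratum
(missingness, partial reporting, the complete flag), and reports the match
rate over all strata and over complete strata only, plus concordance
diagnostics at the passes that relaxed UCOD (2a, 3b) and the death date (2d).
Tables land under results/evaluation/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vetlink.engine import LinkageResult
from vetlink.evaluate import (
    concordance_report,
    profile_missingness,
    profile_strata,
    stage_breakdown,
    state_year_rates,
)
from vetlink.records import filter_eligible, read_harmonized_csv
from vetlink.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]


def load_result(data_dir: Path, linkage_dir: Path):
    mdr = filter_eligible(read_harmonized_csv(data_dir / "mdr.csv"))
    nvdrs = filter_eligible(read_harmonized_csv(data_dir / "nvdrs.csv"))
    matches = pd.read_csv(linkage_dir / "matches.csv")
    linked_m = set(matches["mdr_record_id"])
    linked_n = set(matches["nvdrs_record_id"])
    result = LinkageResult(
        matches=matches,
        stage_counts=pd.read_csv(linkage_dir / "stage_counts.csv"),
        duplicate_audit=pd.read_csv(linkage_dir / "duplicates.csv"),
        unmatched_mdr=mdr[~mdr["record_id"].isin(linked_m)],
        unmatched_nvdrs=nvdrs[~nvdrs["record_id"].isin(linked_n)],
    )
    return mdr, nvdrs, result


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--linkage", type=Path, default=ROOT / "results" / "linkage")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "evaluation")
    args = parser.parse_args()

    mdr, nvdrs, result = load_result(args.data, args.linkage)
    cfg = SimulationConfig.from_yaml(args.data / "config.yaml")
    profiles = profile_strata(nvdrs, cfg.partial_strata())

    breakdown_all = stage_breakdown(result, mdr)
    breakdown_complete = stage_breakdown(result, mdr, profiles, restrict_to_complete=True)
    rates = state_year_rates(result, mdr)
    concordance = concordance_report(result, mdr, nvdrs)
    missingness = profile_missingness(pd.concat([mdr, nvdrs]))

    args.out.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("strata_profiles.csv", profiles),
        ("stage_breakdown_all.csv", breakdown_all),
        ("stage_breakdown_complete.csv", breakdown_complete),
        ("state_year_rates.csv", rates),
        ("concordance.csv", concordance),
        ("missingness.csv", missingness),
    ):
        df.to_csv(args.out / name, index=False, lineterminator="\n")

    n_complete = int(profiles["complete"].sum())
    n_partial = int(profiles["partial_reporting"].sum())
    print(
        f"strata: {len(profiles)} total, {n_complete} complete, "
        f"{len(profiles) - n_complete} excluded "
        f"({n_partial} partial-reporting, "
        f"{len(profiles) - n_complete - n_partial} high-missingness)"
    )
    print("\nMDR records linked, all strata:")
    print(breakdown_all.to_string(index=False))
    print("\nMDR records linked, complete strata only:")
    print(breakdown_complete.to_string(index=False))
    print("\nConcordance at relaxed passes:")
    print(concordance.to_string(index=False))


if __name__ == "__main__":
    main()
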