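#!/usr/bin/env python
"""Run the seven-pass deterministic linkage on the simulated registries.

Reads results/data/, links within state-year strata (stage 1 exact, stages
2a-2d probable, 3a-3b possible), arbitrates duplicate groups, and writes
matches, per-stage counts, the duplicate audit trail and unmatched records
under results/linkage/.
"""

import argparse
from pathlib import Path

from vetlink.engine import run_linkage
from vetlink.evaluate import match_rate
from vetlink.records import filter_eligible, read_harmonized_csv
from vetlink.resolve import summarize_resolutions

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "linkage")
    args = parser.parse_args()

    mdr = filter_eligible(read_harmonized_csv(args.data / "mdr.csv"))
    nvdrs = filter_eligible(read_harmonized_csv(args.data / "nvdrs.csv"))
    result = run_linkage(mdr, nvdrs)

    args.out.mkdir(parents=True, exist_ok=True)
    result.matches.to_csv(args.out / "matches.csv", index=False, lineterminator="\n")
    result.stage_counts.to_csv(
        args.out / "stage_counts.csv", index=False, lineterminator="\n"
    )
    result.duplicate_audit.to_csv(
        args.out / "duplicates.csv", index=False, lineterminator="\n"
    )
    summarize_resolutions(result.duplicate_audit).to_csv(
        args.out / "duplicate_resolution_summary.csv", index=False, lineterminator="\n"
    )
    for name, df in (
        ("unmatched_mdr.csv", result.unmatched_mdr),
        ("unmatched_nvdrs.csv", result.unmatched_nvdrs),
    ):
        df[["record_id", "state", "year"]].to_csv(
            args.out / name, index=False, lineterminator="\n"
        )

    rate = match_rate(result.n_matches, len(mdr))
    print(f"linked {result.n_matches} of {len(mdr)} MDR records ({rate}%)")
    print(result.stage_counts.to_string(index=False))
    n_groups = len(result.duplicate_audit)
    n_resolved = int((result.duplicate_audit["outcome"] == "resolved").sum()) if n_groups else 0
    print(f"duplicate groups: {n_groups} reviewed, {n_resolved} resolved")


if __name__ == "__main__":
    main()
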