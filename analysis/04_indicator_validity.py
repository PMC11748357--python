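#!/usr/bin/env python
"""Assess the NVDRS-style military-history indicator against linked status.

Within complete state-years, linked records define true Veterans; the
indicator's accuracy, sensitivity, specificity, PPV and NPV are computed
overall, by sex and by age band, separately for suicides and undetermined-
intent deaths, each with a 95% Wilson CI. Writes results/validity/validity.csv
and prints the stratified table.
"""

import argparse
from pathlib import Path

from vetlink.evaluate import profile_strata
from vetlink.simulate import SimulationConfig
from vetlink.validity import build_validity_tables

import importlib.util
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "analysis"))
_spec = importlib.util.spec_from_file_location(
    "linkage_success", ROOT / "analysis" / "03_linkage_success.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_result = _mod.load_result


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--linkage", type=Path, default=ROOT / "results" / "linkage")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "validity")
    parser.add_argument(
        "--ci-method", default="wilson", choices=["wilson", "clopper-pearson"]
    )
    args = parser.parse_args()

    mdr, nvdrs, result = load_result(args.data, args.linkage)
    cfg = SimulationConfig.from_yaml(args.data / "config.yaml")
    profiles = profile_strata(nvdrs, cfg.partial_strata())
    tables = build_validity_tables(result, mdr, nvdrs, profiles, args.ci_method)

    args.out.mkdir(parents=True, exist_ok=True)
    tables.to_csv(args.out / "validity.csv", index=False, lineterminator="\n")

    show = tables[
        ["manner", "sex", "age_band", "n_mdr_veterans",
         "accuracy_pct", "sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct"]
    ]
    print("indicator validity within complete state-years (percent):")
    print(show.to_string(index=False))
    overall = tables[
        (tables["manner"] == "all") & (tables["sex"] == "all")
        & (tables["age_band"] == "all")
    ].iloc[0]
    print(
        f"\noverall: sensitivity {overall['sensitivity_pct']}% "
        f"({overall['sensitivity_ci_low']}-{overall['sensitivity_ci_high']}), "
        f"specificity {overall['specificity_pct']}% "
        f"({overall['specificity_ci_low']}-{overall['specificity_ci_high']})"
    )


if __name__ == "__main__":
    main()
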