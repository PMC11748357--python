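"""End-to-end orchestration: simulate -> link -> evaluate -> validity -> report.

Every artifact the run produces is listed in a manifest with its row count
and content hash, so a rerun under the same seed can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluate, records, validity
from .engine import run_linkage
from .resolve import summarize_resolutions
from .simulate import SimulationConfig, default_study_config, simulate, write_outputs
from .stages import stage_sequence

log = logging.getLogger("vetlink")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI flags override config-file keys)."""

    out_dir: Path
    seed: int = 0
    sim: SimulationConfig | None = None  # None -> load mdr/nvdrs paths instead
    mdr_path: Path | None = None
    nvdrs_path: Path | None = None
    stage_ids: list[str] | None = None
    completeness_threshold: float = evaluate.DEFAULT_COMPLETENESS_THRESHOLD
    partial_reporting: list[tuple[str, int]] = field(default_factory=list)
    ci_method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0.0 < float(self.completeness_threshold) < 1.0:
            raise ValueError("completeness_threshold must lie in (0, 1)")
        self.out_dir = Path(self.out_dir)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _file_entry(path: Path, n_rows: int | None = None) -> dict:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    entry = {"sha256": digest}
    if n_rows is not None:
        entry["rows"] = int(n_rows)
    return entry


def load_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, int]]]:
    """Produce the harmonized, eligibility-filtered input tables."""
    if cfg.sim is not None:
        result = simulate(cfg.sim, seed=cfg.seed)
        write_outputs(result, cfg.out_dir / "data")
        partial = cfg.sim.partial_strata()
        mdr, nvdrs = result.mdr, result.nvdrs
    else:
        if cfg.mdr_path is None or cfg.nvdrs_path is None:
            raise ValueError("either a simulation config or both input paths are required")
        mdr, mdr_rej = records.read_registry_csv(cfg.mdr_path, "MDR")
        nvdrs, nv_rej = records.read_registry_csv(cfg.nvdrs_path, "NVDRS")
        for name, rej in (("MDR", mdr_rej), ("NVDRS", nv_rej)):
            if len(rej):
                log.warning("%s: rejected %d records at harmonization", name, len(rej))
        partial = list(cfg.partial_reporting)
    return records.filter_eligible(mdr), records.filter_eligible(nvdrs), partial


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole analysis and write every artifact plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mdr, nvdrs, partial = load_inputs(cfg)
    log.info("eligible records: %d MDR, %d NVDRS", len(mdr), len(nvdrs))

    stages = stage_sequence(cfg.stage_ids)
    result = run_linkage(mdr, nvdrs, stages)
    log.info(
        "linked %d of %d MDR records; %d duplicate groups",
        result.n_matches,
        len(mdr),
        len(result.duplicate_audit),
    )

    profiles = evaluate.profile_strata(nvdrs, partial, cfg.completeness_threshold)
    breakdown_all = evaluate.stage_breakdown(result, mdr)
    breakdown_complete = evaluate.stage_breakdown(
        result, mdr, profiles, restrict_to_complete=True
    )
    rates = evaluate.state_year_rates(result, mdr)
    concordance = evaluate.concordance_report(result, mdr, nvdrs)
    missingness = evaluate.profile_missingness(pd.concat([mdr, nvdrs]))
    duplicates_summary = summarize_resolutions(result.duplicate_audit)
    validity_tables = validity.build_validity_tables(
        result, mdr, nvdrs, profiles, ci_method=cfg.ci_method
    )

    artifacts = {
        "matches.csv": result.matches,
        "stage_counts.csv": result.stage_counts,
        "duplicates.csv": result.duplicate_audit,
        "duplicate_resolution_summary.csv": duplicates_summary,
        "unmatched_mdr.csv": result.unmatched_mdr[["record_id", "state", "year"]],
        "unmatched_nvdrs.csv": result.unmatched_nvdrs[["record_id", "state", "year"]],
        "strata_profiles.csv": profiles,
        "stage_breakdown_all.csv": breakdown_all,
        "stage_breakdown_complete.csv": breakdown_complete,
        "state_year_rates.csv": rates,
        "concordance.csv": concordance,
        "missingness.csv": missingness,
        "validity.csv": validity_tables,
    }
    manifest: dict = {"files": {}, "seed": int(cfg.seed)}
    for name, df in artifacts.items():
        path = out / name
        _write(df, path)
        manifest["files"][name] = _file_entry(path, len(df))
    if cfg.sim is not None:
        for name in ("mdr.csv", "nvdrs.csv", "truth.csv", "config.yaml"):
            path = out / "data" / name
            manifest["files"][f"data/{name}"] = _file_entry(path)
        manifest["config_hash"] = cfg.sim.content_hash()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def default_run_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    return RunConfig(out_dir=Path(out_dir), seed=seed, sim=default_study_config(seed))
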