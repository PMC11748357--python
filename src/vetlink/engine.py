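"""The multi-pass deterministic linkage engine.

Each pass joins the unmatched residue of the MDR and NVDRS pools on a
concatenated key (state-year stratum plus the pass's key variables). Keys
occurring exactly once on each side yield a match; keys with several possible
pairings form duplicate groups arbitrated by :mod:`vetlink.resolve`. Matched
records are removed from both pools before the next pass; unresolved
duplicates are released back and carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .resolve import DuplicateGroup, Resolution, resolve_group
from .stages import DEFAULT_STAGES, StageSpec, stage_keys

MATCH_COLUMNS = (
    "mdr_record_id",
    "nvdrs_record_id",
    "state",
    "year",
    "stage_id",
    "tier",
    "resolution",
)

AUDIT_COLUMNS = (
    "group_id",
    "stage_id",
    "state",
    "year",
    "key",
    "mdr_ids",
    "nvdrs_ids",
    "outcome",
    "rule",
    "reason",
    "mdr_record_id",
    "nvdrs_record_id",
)


@dataclass
class PassResult:
    spec: StageSpec
    match_pairs: pd.DataFrame
    duplicate_groups: list[DuplicateGroup]
    resolutions: list[Resolution]
    mdr_remaining: pd.DataFrame
    nvdrs_remaining: pd.DataFrame


@dataclass
class LinkageResult:
    """Everything a full run produced: matches, per-stage counts, audit trail."""

    matches: pd.DataFrame
    stage_counts: pd.DataFrame
    duplicate_audit: pd.DataFrame
    unmatched_mdr: pd.DataFrame
    unmatched_nvdrs: pd.DataFrame
    stages: tuple[StageSpec, ...] = field(default=DEFAULT_STAGES)

    @property
    def n_matches(self) -> int:
        return len(self.matches)


def _empty_matches() -> pd.DataFrame:
    return pd.DataFrame(columns=list(MATCH_COLUMNS))


def run_pass(
    mdr_pool: pd.DataFrame,
    nvdrs_pool: pd.DataFrame,
    spec: StageSpec,
) -> PassResult:
    """Execute one linkage pass over the current unmatched pools."""
    nvdrs_candidates = nvdrs_pool
    if spec.require_nvdrs_dmb_filn_missing:
        mask = nvdrs_pool["dmb"].isna() & nvdrs_pool["filn"].isna()
        nvdrs_candidates = nvdrs_pool.loc[mask]

    m_keys = stage_keys(mdr_pool, spec) if len(mdr_pool) else pd.Series(dtype=object)
    n_keys = (
        stage_keys(nvdrs_candidates, spec)
        if len(nvdrs_candidates)
        else pd.Series(dtype=object)
    )

    m = pd.DataFrame(
        {
            "record_id": mdr_pool["record_id"],
            "key": m_keys,
            "state": mdr_pool["state"],
            "year": mdr_pool["year"],
        }
    ).dropna(subset=["key"])
    n = pd.DataFrame(
        {
            "record_id": nvdrs_candidates["record_id"],
            "key": n_keys,
            "state": nvdrs_candidates["state"],
            "year": nvdrs_candidates["year"],
        }
    ).dropna(subset=["key"])

    m_counts = m["key"].value_counts()
    n_counts = n["key"].value_counts()
    common = m_counts.index.intersection(n_counts.index)

    mc = m_counts.reindex(common)
    nc = n_counts.reindex(common)
    unique_keys = common[(mc == 1) & (nc == 1)]
    dup_keys = sorted(common[(mc * nc) >= 2])

    pairs = (
        m[m["key"].isin(unique_keys)]
        .merge(n[n["key"].isin(unique_keys)], on="key", suffixes=("_mdr", "_nvdrs"))
        .sort_values("key")
    )
    # stratum fence: the key embeds state-year, so this can never fire
    if len(pairs) and not (
        (pairs["state_mdr"] == pairs["state_nvdrs"]).all()
        and (pairs["year_mdr"] == pairs["year_nvdrs"]).all()
    ):
        raise AssertionError("cross-stratum key collision")

    unique_matches = pd.DataFrame(
        {
            "mdr_record_id": pairs["record_id_mdr"].to_numpy(),
            "nvdrs_record_id": pairs["record_id_nvdrs"].to_numpy(),
            "state": pairs["state_mdr"].to_numpy(),
            "year": pairs["year_mdr"].astype(int).to_numpy(),
            "stage_id": spec.stage_id,
            "tier": spec.tier,
            "resolution": "unique_key",
        },
        columns=list(MATCH_COLUMNS),
    )

    match_rows = []
    dup_m = m[m["key"].isin(dup_keys)]
    dup_n = n[n["key"].isin(dup_keys)]
    mdr_by_id = mdr_pool[mdr_pool["record_id"].isin(dup_m["record_id"])].set_index(
        "record_id", drop=False
    )
    nv_by_id = nvdrs_pool[nvdrs_pool["record_id"].isin(dup_n["record_id"])].set_index(
        "record_id", drop=False
    )

    # duplicate groups: several possible pairings under one key
    groups: list[DuplicateGroup] = []
    resolutions: list[Resolution] = []
    m_by_key = dup_m.groupby("key")["record_id"].apply(list)
    n_by_key = dup_n.groupby("key")["record_id"].apply(list)
    for key in dup_keys:
        mdr_ids = tuple(sorted(m_by_key[key]))
        nvdrs_ids = tuple(sorted(n_by_key[key]))
        any_rec = mdr_by_id.loc[mdr_ids[0]]
        group = DuplicateGroup(
            state=any_rec["state"],
            year=int(any_rec["year"]),
            stage_id=spec.stage_id,
            key=key,
            mdr_ids=mdr_ids,
            nvdrs_ids=nvdrs_ids,
        )
        groups.append(group)
        lookup = {rid: mdr_by_id.loc[rid] for rid in mdr_ids}
        lookup.update({rid: nv_by_id.loc[rid] for rid in nvdrs_ids})
        res = resolve_group(group, lookup, spec)
        resolutions.append(res)
        if res.resolved:
            m_id, n_id = res.pair
            match_rows.append(
                {
                    "mdr_record_id": m_id,
                    "nvdrs_record_id": n_id,
                    "state": group.state,
                    "year": group.year,
                    "stage_id": spec.stage_id,
                    "tier": spec.tier,
                    "resolution": res.rule,
                }
            )

    resolved_matches = (
        pd.DataFrame(match_rows, columns=list(MATCH_COLUMNS))
        if match_rows
        else _empty_matches()
    )
    match_pairs = pd.concat(
        [unique_matches, resolved_matches], ignore_index=True
    )
    matched_mdr = set(match_pairs["mdr_record_id"])
    matched_nvdrs = set(match_pairs["nvdrs_record_id"])

    mdr_remaining = mdr_pool.loc[~mdr_pool["record_id"].isin(matched_mdr)]
    nvdrs_remaining = nvdrs_pool.loc[~nvdrs_pool["record_id"].isin(matched_nvdrs)]

    return PassResult(
        spec=spec,
        match_pairs=match_pairs,
        duplicate_groups=groups,
        resolutions=resolutions,
        mdr_remaining=mdr_remaining,
        nvdrs_remaining=nvdrs_remaining,
    )


def run_linkage(
    mdr_table: pd.DataFrame,
    nvdrs_table: pd.DataFrame,
    stages: tuple[StageSpec, ...] = DEFAULT_STAGES,
) -> LinkageResult:
    """Run the full pass sequence and assemble the audit trail.

    Input tables must be harmonized and eligibility-filtered. The result's
    matches are one-to-one: no record id appears twice.
    """
    mdr_pool = mdr_table
    nvdrs_pool = nvdrs_table
    all_matches = []
    stage_rows = []
    audit_rows = []
    group_seq = 0

    for spec in stages:
        result = run_pass(mdr_pool, nvdrs_pool, spec)
        all_matches.append(result.match_pairs)
        n_unique = int((result.match_pairs["resolution"] == "unique_key").sum())
        n_resolved = sum(1 for r in result.resolutions if r.resolved)
        stage_rows.append(
            {
                "stage_id": spec.stage_id,
                "tier": spec.tier,
                "n_matched": len(result.match_pairs),
                "n_unique_key": n_unique,
                "n_duplicate_groups": len(result.duplicate_groups),
                "n_groups_resolved": n_resolved,
                "n_groups_unresolved": len(result.duplicate_groups) - n_resolved,
            }
        )
        for res in result.resolutions:
            group_seq += 1
            audit_rows.append(
                {
                    "group_id": f"G{group_seq:04d}",
                    "stage_id": spec.stage_id,
                    "state": res.group.state,
                    "year": res.group.year,
                    "key": res.group.key,
                    "mdr_ids": ";".join(res.group.mdr_ids),
                    "nvdrs_ids": ";".join(res.group.nvdrs_ids),
                    "outcome": "resolved" if res.resolved else "unresolved",
                    "rule": res.rule,
                    "reason": res.reason,
                    "mdr_record_id": res.pair[0] if res.resolved else None,
                    "nvdrs_record_id": res.pair[1] if res.resolved else None,
                }
            )
        mdr_pool = result.mdr_remaining
        nvdrs_pool = result.nvdrs_remaining

    matches = (
        pd.concat(all_matches, ignore_index=True) if all_matches else _empty_matches()
    )
    if matches["mdr_record_id"].duplicated().any() or matches[
        "nvdrs_record_id"
    ].duplicated().any():
        raise AssertionError("one-to-one violation: a record id matched twice")

    stage_counts = pd.DataFrame(stage_rows)
    duplicate_audit = pd.DataFrame(audit_rows, columns=list(AUDIT_COLUMNS))
    return LinkageResult(
        matches=matches,
        stage_counts=stage_counts,
        duplicate_audit=duplicate_audit,
        unmatched_mdr=mdr_pool.reset_index(drop=True),
        unmatched_nvdrs=nvdrs_pool.reset_index(drop=True),
        stages=stages,
    )
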