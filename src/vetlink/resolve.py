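"""Arbitration of duplicate match groups.

When a pass's key joins more than one possible pairing (two NVDRS records
against one MDR record, or vice versa), a deterministic cascade codifies the
manual review the linkage protocol prescribes:

1. **MCOD containment** (``mcod_rule``): a pairing is supported when every
   present MDR multiple-cause code appears among the NVDRS record's present
   codes — missing NVDRS *slots* never block, and a fully missing MCOD on
   either side is uninformative. Resolve if exactly one pairing is supported.
2. **Field review** (``field_review_rule``): among the variables this pass
   allowed to disagree, resolve if exactly one pairing agrees exactly on all
   of them; failing that, when the death date was relaxed, resolve on the
   unique strictly smallest absolute date difference.
3. **Military indicator** (``military_rule``): with a single MDR candidate,
   resolve if exactly one NVDRS candidate says "yes" to military history.

If every reviewed NVDRS field is missing the group is unresolved for
insufficient information; unresolved members return to the pool for later
passes. The cascade is invariant to candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import pandas as pd

from .records import mcod_set
from .stages import StageSpec


@dataclass(frozen=True)
class DuplicateGroup:
    """All records sharing one pass key when more than one pairing is possible."""

    state: str
    year: int
    stage_id: str
    key: str
    mdr_ids: tuple[str, ...]
    nvdrs_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.mdr_ids) * len(self.nvdrs_ids) < 2:
            raise ValueError("a duplicate group needs at least two possible pairings")


@dataclass(frozen=True)
class Resolution:
    group: DuplicateGroup
    pair: tuple[str, str] | None  # (mdr_id, nvdrs_id) when resolved
    rule: str | None  # mcod_rule | field_review_rule | military_rule
    reason: str

    @property
    def resolved(self) -> bool:
        return self.pair is not None


def _values_equal(a, b) -> bool:
    if pd.isna(a) or pd.isna(b):
        return False
    return a == b


def resolve_group(
    group: DuplicateGroup,
    records: Mapping[str, pd.Series],
    spec: StageSpec,
) -> Resolution:
    """Apply the three-rule cascade to one duplicate group.

    ``records`` maps record_id to the harmonized row for every group member.
    """
    pairings = sorted(product(sorted(group.mdr_ids), sorted(group.nvdrs_ids)))
    informative = False

    # Rule 1: MCOD containment, MDR codes within NVDRS codes.
    supported = []
    for m_id, n_id in pairings:
        m_codes = mcod_set(records[m_id])
        n_codes = mcod_set(records[n_id])
        if not m_codes or not n_codes:
            continue  # uninformative pairing
        informative = True
        if m_codes <= n_codes:
            supported.append((m_id, n_id))
    if len(supported) == 1:
        return Resolution(group, supported[0], "mcod_rule", "unique MCOD containment")

    # Rule 2: review of the variables this pass allowed to mismatch.
    relaxed = spec.relaxed_variables
    if relaxed:
        exact = []
        for m_id, n_id in pairings:
            m, n = records[m_id], records[n_id]
            if any(pd.notna(n[v]) for v in relaxed):
                informative = True
            if all(_values_equal(m[v], n[v]) for v in relaxed):
                exact.append((m_id, n_id))
        if len(exact) == 1:
            return Resolution(
                group, exact[0], "field_review_rule", "unique exact agreement on relaxed variables"
            )
        if "death_date" in relaxed:
            diffs = {}
            for m_id, n_id in pairings:
                m, n = records[m_id], records[n_id]
                if pd.notna(m["death_date"]) and pd.notna(n["death_date"]):
                    diffs[(m_id, n_id)] = abs(
                        (pd.Timestamp(n["death_date"]) - pd.Timestamp(m["death_date"])).days
                    )
            if diffs:
                informative = True
                best = min(diffs.values())
                winners = [p for p, d in diffs.items() if d == best]
                if len(winners) == 1:
                    return Resolution(
                        group,
                        winners[0],
                        "field_review_rule",
                        "unique minimal death-date difference",
                    )

    # Rule 3: military-history indicator (NVDRS attribute; needs one MDR side).
    if len(group.mdr_ids) == 1:
        statuses = {
            n_id: records[n_id]["military_history"] for n_id in group.nvdrs_ids
        }
        if any(s in ("yes", "no") for s in statuses.values()):
            informative = True
        yes = sorted(n_id for n_id, s in statuses.items() if s == "yes")
        if len(yes) == 1:
            return Resolution(
                group,
                (group.mdr_ids[0], yes[0]),
                "military_rule",
                "single candidate with military history = yes",
            )

    reason = (
        "ambiguous after all rules"
        if informative
        else "insufficient information (all reviewed NVDRS fields missing)"
    )
    return Resolution(group, None, None, reason)


def summarize_resolutions(duplicate_audit: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of resolved groups by resolution method.

    Takes the duplicate audit table of a linkage run (one row per group) and
    returns one row per rule with ``n_resolved`` and ``pct_of_resolved``
    (half-up, 2 dp). Empty input (or no resolved groups) gives an empty frame.
    """
    from .evaluate import percent

    cols = ["rule", "n_resolved", "pct_of_resolved"]
    if duplicate_audit.empty:
        return pd.DataFrame(columns=cols)
    resolved = duplicate_audit[duplicate_audit["outcome"] == "resolved"]
    total = len(resolved)
    if total == 0:
        return pd.DataFrame(columns=cols)
    counts = resolved.groupby("rule").size().sort_index()
    return pd.DataFrame(
        {
            "rule": counts.index,
            "n_resolved": counts.to_numpy(),
            "pct_of_resolved": [percent(c, total) for c in counts],
        }
    ).reset_index(drop=True)
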