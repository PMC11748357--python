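"""Linkage-success evaluation.

Match percentages overall / by tier / by state-year, stratum completeness
profiling (partial-reporting flags and the >10%-missing-two-variables
filter), per-variable missingness, and concordance diagnostics on the
variables each pass allowed to disagree.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .engine import LinkageResult
from .records import LINKAGE_VARIABLES

#: strata with more than this share of records missing >= 2 linkage variables
#: are not "complete" (strictly greater than; a stratum at exactly the
#: threshold passes, which the profile flags for transparency)
DEFAULT_COMPLETENESS_THRESHOLD = 0.10


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention for all reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact ratio as a half-up-rounded percentage."""
    frac = Decimal(int(numerator) * 100) / Decimal(int(denominator))
    q = Decimal(1).scaleb(-ndigits)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def match_rate(n_matched: int, n_total: int) -> float | None:
    """Share of records linked, as a percentage at 2 dp.

    An empty denominator has no defined rate and returns ``None`` (reported
    downstream as not-applicable, never as 0).
    """
    if n_total == 0:
        return None
    if n_matched < 0 or n_matched > n_total:
        raise ValueError("n_matched must lie in [0, n_total]")
    return percent(n_matched, n_total)


def profile_strata(
    nvdrs_table: pd.DataFrame,
    partial_reporting: Iterable[tuple[str, int]] = (),
    threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
) -> pd.DataFrame:
    """Per-stratum data-quality profile of the NVDRS table.

    One row per state-year with record count, per-variable missing
    proportions, the share of records missing two or more of the six linkage
    variables, the partial-reporting flag (supplied via configuration, never
    inferred), and the derived ``complete`` flag.
    """
    partial = {(s, int(y)) for s, y in partial_reporting}
    rows = []
    grouped = nvdrs_table.groupby(["state", "year"], sort=True)
    for (state, year), g in grouped:
        n = len(g)
        miss = {v: g[v].isna().sum() for v in LINKAGE_VARIABLES}
        n_missing_2plus = int(
            (sum(g[v].isna().astype(int) for v in LINKAGE_VARIABLES) >= 2).sum()
        )
        prop2 = n_missing_2plus / n if n else 1.0
        is_partial = (state, int(year)) in partial
        rows.append(
            {
                "state": state,
                "year": int(year),
                "n_nvdrs_records": n,
                **{f"prop_missing_{v}": (miss[v] / n if n else 1.0) for v in LINKAGE_VARIABLES},
                "prop_missing_2plus": prop2,
                "at_threshold": bool(n and abs(prop2 - threshold) < 1e-12),
                "partial_reporting": is_partial,
                "complete": bool(n > 0 and not is_partial and prop2 <= threshold),
            }
        )
    # strata on the partial list with zero records still deserve a row
    for state, year in sorted(partial):
        if not ((nvdrs_table["state"] == state) & (nvdrs_table["year"] == year)).any():
            rows.append(
                {
                    "state": state,
                    "year": year,
                    "n_nvdrs_records": 0,
                    **{f"prop_missing_{v}": 1.0 for v in LINKAGE_VARIABLES},
                    "prop_missing_2plus": 1.0,
                    "at_threshold": False,
                    "partial_reporting": True,
                    "complete": False,
                }
            )
    return pd.DataFrame(rows).sort_values(["state", "year"]).reset_index(drop=True)


def complete_strata(profiles: pd.DataFrame) -> set[tuple[str, int]]:
    sel = profiles[profiles["complete"]]
    return {(s, int(y)) for s, y in zip(sel["state"], sel["year"])}


def stage_breakdown(
    result: LinkageResult,
    mdr_table: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    restrict_to_complete: bool = False,
) -> pd.DataFrame:
    """Percentages of MDR records matched by tier (exact/probable/possible).

    With ``restrict_to_complete`` both the matches and the MDR denominator are
    limited to complete state-years, mirroring the complete-reporting view of
    linkage success. Tier shares plus the unmatched share sum to 100 within
    rounding.
    """
    matches = result.matches
    mdr = mdr_table
    if restrict_to_complete:
        if profiles is None:
            raise ValueError("profiles are required to restrict to complete strata")
        keep = complete_strata(profiles)
        matches = matches[
            [(s, int(y)) in keep for s, y in zip(matches["state"], matches["year"])]
        ]
        mdr = mdr[[(s, int(y)) in keep for s, y in zip(mdr["state"], mdr["year"])]]

    total = len(mdr)
    rows = []
    matched = 0
    for tier in ("exact", "probable", "possible"):
        k = int((matches["tier"] == tier).sum())
        matched += k
        rows.append(
            {
                "tier": tier,
                "n_matched": k,
                "pct_of_mdr": match_rate(k, total),
            }
        )
    rows.append(
        {
            "tier": "unmatched",
            "n_matched": total - matched,
            "pct_of_mdr": match_rate(total - matched, total),
        }
    )
    rows.append(
        {
            "tier": "all_matched",
            "n_matched": matched,
            "pct_of_mdr": match_rate(matched, total),
        }
    )
    out = pd.DataFrame(rows)
    out["n_mdr_total"] = total
    return out


def state_year_rates(result: LinkageResult, mdr_table: pd.DataFrame) -> pd.DataFrame:
    """Linked share of MDR records per state-year stratum."""
    totals = mdr_table.groupby(["state", "year"]).size()
    linked = result.matches.groupby(["state", "year"]).size()
    rows = []
    for (state, year), n_total in totals.sort_index().items():
        k = int(linked.get((state, year), 0))
        rows.append(
            {
                "state": state,
                "year": int(year),
                "n_mdr": int(n_total),
                "n_linked": k,
                "pct_linked": match_rate(k, int(n_total)),
            }
        )
    return pd.DataFrame(rows)


def concordance_report(
    result: LinkageResult,
    mdr_table: pd.DataFrame,
    nvdrs_table: pd.DataFrame,
    stage_ids: tuple[str, ...] = ("S2a", "S2d", "S3b"),
    date_window_days: int = 30,
) -> pd.DataFrame:
    """Consistency diagnostics on relaxed variables at selected passes.

    For passes that relaxed the UCOD (S2a, S3b): how many linked pairs had the
    NVDRS UCOD missing vs present-but-different vs present-and-equal (the last
    arises only from unresolved duplicates pushed past an earlier pass). For
    the pass that relaxed the death date (S2d): missing NVDRS date,
    difference within the window (inclusive), difference beyond it.
    """
    m_idx = mdr_table.set_index("record_id")
    n_idx = nvdrs_table.set_index("record_id")
    rows = []
    for stage_id in stage_ids:
        pairs = result.matches[result.matches["stage_id"] == stage_id]
        n_pairs = len(pairs)
        m_rec = m_idx.loc[pairs["mdr_record_id"]]
        n_rec = n_idx.loc[pairs["nvdrs_record_id"]]
        if stage_id in ("S2a", "S3b"):
            nv = n_rec["ucod"].to_numpy(dtype=object)
            md = m_rec["ucod"].to_numpy(dtype=object)
            missing = int(pd.isna(nv).sum())
            different = sum(
                1
                for a, b in zip(nv, md)
                if not pd.isna(a) and (pd.isna(b) or a != b)
            )
            equal = n_pairs - missing - different
            for bucket, count in (
                ("nvdrs_ucod_missing", missing),
                ("ucod_different", different),
                ("ucod_equal", equal),
            ):
                rows.append(
                    {
                        "stage_id": stage_id,
                        "variable": "ucod",
                        "bucket": bucket,
                        "n": count,
                        "pct_of_pairs": match_rate(count, n_pairs),
                        "n_pairs": n_pairs,
                    }
                )
        if stage_id == "S2d":
            nv = pd.Series(n_rec["death_date"].to_numpy(), index=range(n_pairs))
            md = pd.Series(m_rec["death_date"].to_numpy(), index=range(n_pairs))
            missing = int(nv.isna().sum())
            delta = (nv - md).dt.days.abs()
            within = int(((delta <= date_window_days) & nv.notna()).sum())
            beyond = int((delta > date_window_days).sum())
            for bucket, count in (
                ("nvdrs_date_missing", missing),
                (f"within_{date_window_days}_days", within),
                (f"beyond_{date_window_days}_days", beyond),
            ):
                rows.append(
                    {
                        "stage_id": stage_id,
                        "variable": "death_date",
                        "bucket": bucket,
                        "n": count,
                        "pct_of_pairs": match_rate(count, n_pairs),
                        "n_pairs": n_pairs,
                    }
                )
    return pd.DataFrame(rows)


def profile_missingness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable missing counts and percentages, by source."""
    rows = []
    for source, g in table.groupby("source"):
        n = len(g)
        for var in LINKAGE_VARIABLES:
            k = int(g[var].isna().sum())
            rows.append(
                {
                    "source": source,
                    "variable": var,
                    "n_records": n,
                    "n_missing": k,
                    "pct_missing": match_rate(k, n) if n else None,
                }
            )
    return pd.DataFrame(rows)
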