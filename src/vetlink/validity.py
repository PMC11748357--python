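"""Validity of the NVDRS military-history indicator against linked Veteran status.

Within complete state-years, linked MDR records define the status-positive
(Veteran) set and unlinked NVDRS records are treated as status-negative — the
only operationalization available without identifiers. Contingency counts are
stratified overall, by sex, and by age band (17-39, 40-64, 65+), separately
by manner of death, each record stratified by its own source's fields.

Metrics (all percentages with 95% CIs, Wilson score by default):

* sensitivity  = linked "yes" / all MDR Veteran deaths in the group
  (unlinked MDR Veterans count as false negatives)
* specificity  = unlinked "no" / all unlinked NVDRS records
* accuracy     = (linked "yes" + unlinked "no") / all NVDRS records in scope
* PPV          = linked "yes" / all "yes" records
* NPV          = unlinked "no" / all "no" records
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .engine import LinkageResult
from .evaluate import complete_strata, percent, round_half_up

AGE_BANDS = (("17-39", 17, 39), ("40-64", 40, 64), ("65+", 65, None))

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")

COUNT_COLUMNS = (
    "n_mdr_veterans",
    "n_linked_yes",
    "n_linked_no",
    "n_linked_unknown",
    "n_unlinked_yes",
    "n_unlinked_no",
    "n_unlinked_unknown",
)


@dataclass(frozen=True)
class ValidityTable:
    """Contingency counts for one stratum, plus the stratum labels."""

    manner: str  # "suicide" | "undetermined" | "all"
    sex: str  # "male" | "female" | "all"
    age_band: str  # "17-39" | "40-64" | "65+" | "all"
    n_mdr_veterans: int
    n_linked_yes: int
    n_linked_no: int
    n_linked_unknown: int
    n_unlinked_yes: int
    n_unlinked_no: int
    n_unlinked_unknown: int

    @property
    def n_linked(self) -> int:
        return self.n_linked_yes + self.n_linked_no + self.n_linked_unknown

    @property
    def n_unlinked(self) -> int:
        return self.n_unlinked_yes + self.n_unlinked_no + self.n_unlinked_unknown

    @property
    def n_nvdrs(self) -> int:
        return self.n_linked + self.n_unlinked


def age_band(age) -> str | None:
    if pd.isna(age):
        return None
    age = int(age)
    for label, lo, hi in AGE_BANDS:
        if age >= lo and (hi is None or age <= hi):
            return label
    return None


def _ci(count: int, nobs: int, method: str) -> tuple[float, float]:
    method_map = {"wilson": "wilson", "clopper-pearson": "beta", "beta": "beta"}
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=method_map[method])
    return round_half_up(float(lo) * 100), round_half_up(float(hi) * 100)


def wilson_interval(count: int, nobs: int) -> tuple[float, float]:
    """95% Wilson score interval on the proportion scale (not percent)."""
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def metrics_from_table(table: ValidityTable, ci_method: str = "wilson") -> dict:
    """Point estimates (percent, 2 dp) and 95% CIs for the five metrics.

    A zero denominator makes a metric not-applicable (``None``), never 0.
    "Unknown" indicators count against accuracy in both directions but are
    excluded from the PPV/NPV denominators, which range over "yes"/"no"
    records respectively.
    """

    def metric(count: int, nobs: int):
        if nobs == 0:
            return {"estimate": None, "ci_low": None, "ci_high": None, "n": 0}
        lo, hi = _ci(count, nobs, ci_method)
        return {
            "estimate": percent(count, nobs),
            "ci_low": lo,
            "ci_high": hi,
            "n": nobs,
        }

    t = table
    return {
        "accuracy": metric(t.n_linked_yes + t.n_unlinked_no, t.n_nvdrs),
        "sensitivity": metric(t.n_linked_yes, t.n_mdr_veterans),
        "specificity": metric(t.n_unlinked_no, t.n_unlinked),
        "ppv": metric(t.n_linked_yes, t.n_linked_yes + t.n_unlinked_yes),
        "npv": metric(t.n_unlinked_no, t.n_linked_no + t.n_unlinked_no),
    }


def _strata_rows() -> list[tuple[str, str, str]]:
    rows = [("all", "all", "all")]
    for manner in ("suicide", "undetermined"):
        rows.append((manner, "all", "all"))
        for sex in ("female", "male"):
            rows.append((manner, sex, "all"))
        for band, _, _ in AGE_BANDS:
            rows.append((manner, "all", band))
    return rows


def build_validity_tables(
    result: LinkageResult,
    mdr_table: pd.DataFrame,
    nvdrs_table: pd.DataFrame,
    profiles: pd.DataFrame,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Stratified contingency tables with derived metrics, as a flat frame.

    Scope is limited to complete state-years. Each record is stratified by its
    own source's manner, sex and age; records with missing age drop out of
    age-stratified rows only (missing sex likewise for sex rows).
    """
    keep = complete_strata(profiles)

    def in_scope(df: pd.DataFrame) -> pd.DataFrame:
        mask = [(s, int(y)) in keep for s, y in zip(df["state"], df["year"])]
        return df.loc[mask]

    mdr = in_scope(mdr_table).copy()
    nvdrs = in_scope(nvdrs_table).copy()
    mdr["age_band"] = mdr["age_at_death"].map(age_band)
    nvdrs["age_band"] = nvdrs["age_at_death"].map(age_band)

    linked_nvdrs_ids = set(result.matches["nvdrs_record_id"])
    nvdrs["linked"] = nvdrs["record_id"].isin(linked_nvdrs_ids)

    rows = []
    for manner, sex, band in _strata_rows():
        m_sel = mdr
        n_sel = nvdrs
        if manner != "all":
            m_sel = m_sel[m_sel["manner"] == manner]
            n_sel = n_sel[n_sel["manner"] == manner]
        if sex != "all":
            m_sel = m_sel[m_sel["sex"] == sex]
            n_sel = n_sel[n_sel["sex"] == sex]
        if band != "all":
            m_sel = m_sel[m_sel["age_band"] == band]
            n_sel = n_sel[n_sel["age_band"] == band]

        linked = n_sel[n_sel["linked"]]
        unlinked = n_sel[~n_sel["linked"]]
        table = ValidityTable(
            manner=manner,
            sex=sex,
            age_band=band,
            n_mdr_veterans=len(m_sel),
            n_linked_yes=int((linked["military_history"] == "yes").sum()),
            n_linked_no=int((linked["military_history"] == "no").sum()),
            n_linked_unknown=int((linked["military_history"] == "unknown").sum()),
            n_unlinked_yes=int((unlinked["military_history"] == "yes").sum()),
            n_unlinked_no=int((unlinked["military_history"] == "no").sum()),
            n_unlinked_unknown=int((unlinked["military_history"] == "unknown").sum()),
        )
        metrics = metrics_from_table(table, ci_method)
        row = {
            "manner": manner,
            "sex": sex,
            "age_band": band,
            **{c: getattr(table, c) for c in COUNT_COLUMNS},
        }
        for name in METRICS:
            row[f"{name}_pct"] = metrics[name]["estimate"]
            row[f"{name}_ci_low"] = metrics[name]["ci_low"]
            row[f"{name}_ci_high"] = metrics[name]["ci_high"]
        rows.append(row)
    return pd.DataFrame(rows)
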