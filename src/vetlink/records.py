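"""Harmonized decedent records shared by both registries.

Two source tables flow through the pipeline:

* **MDR** — the gold-standard Veteran mortality registry. Raw extracts carry a
  full date of birth, which is reduced at harmonization to the day-of-month of
  birth (``dmb``) plus age at death in completed years, and then discarded so
  no downstream artifact can re-identify a record.
* **NVDRS** — the violent-death registry, which never carries full
  identifiers: only age, sex, day-of-month of birth, first initial of the last
  name (``filn``), dates and ICD-10 cause codes.

After harmonization both sources share one schema
(:data:`HARMONIZED_COLUMNS`), so every later stage is source-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SOURCES = ("MDR", "NVDRS")

#: the six variables every linkage stage draws its key from
LINKAGE_VARIABLES = ("age_at_death", "sex", "ucod", "dmb", "filn", "death_date")

MCOD_COLUMNS = tuple(f"mcod{i}" for i in range(1, 15))

HARMONIZED_COLUMNS = (
    "record_id",
    "source",
    "state",
    "year",
    "death_date",
    "age_at_death",
    "sex",
    "dmb",
    "filn",
    "ucod",
    *MCOD_COLUMNS,
    "manner",
    "military_history",
    "veteran_flag",
)

MANNERS = ("suicide", "undetermined", "other", "unknown")
MILITARY_LEVELS = ("yes", "no", "unknown")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")
_RANGE_RE = re.compile(r"^([A-Z][0-9]{2})\s*-\s*([A-Z][0-9]{2})$")


class SchemaError(ValueError):
    """Raised when an input table violates the documented header contract."""


def canonicalize_icd10(code: str, *, record_id: str | None = None) -> str:
    """Return the canonical rendering of an ICD-10 code: uppercase, no dot.

    Raises ``ValueError`` (naming the record when known) for strings that do
    not parse as an ICD-10 code.
    """
    canon = str(code).strip().upper().replace(".", "")
    if not _ICD10_RE.match(canon):
        where = f" (record {record_id})" if record_id else ""
        raise ValueError(f"malformed ICD-10 code {code!r}{where}")
    return canon


@dataclass(frozen=True)
class CodeTable:
    """ICD-10 groupings used to classify manner of death from the UCOD.

    Entries are single codes (``"U03"``, ``"Y87.0"``) or closed 3-character
    ranges (``"X60-X84"``). A 3-character entry matches any code sharing that
    root; a longer entry matches by prefix. The default groupings are the
    standard CDC suicide / undetermined-intent sets.
    """

    suicide: tuple[str, ...] = ("X60-X84", "Y87.0", "U03")
    undetermined: tuple[str, ...] = ("Y10-Y34", "Y87.2", "Y89.9")

    def __post_init__(self) -> None:
        self._parse(self.suicide)
        self._parse(self.undetermined)
        probes = [e for e in self._probe_codes(self.suicide)] + [
            e for e in self._probe_codes(self.undetermined)
        ]
        for probe in probes:
            if self._matches(probe, self.suicide) and self._matches(
                probe, self.undetermined
            ):
                raise ValueError(
                    f"suicide and undetermined code sets overlap at {probe!r}"
                )

    @staticmethod
    def _parse(entries: Iterable[str]) -> list[tuple[str, str] | str]:
        parsed: list[tuple[str, str] | str] = []
        for entry in entries:
            m = _RANGE_RE.match(entry.strip().upper())
            if m:
                lo, hi = m.group(1), m.group(2)
                if lo > hi:
                    raise ValueError(f"inverted code range {entry!r}")
                parsed.append((lo, hi))
            else:
                parsed.append(canonicalize_icd10(entry))
        return parsed

    @classmethod
    def _probe_codes(cls, entries: Iterable[str]) -> list[str]:
        probes = []
        for e in cls._parse(entries):
            if isinstance(e, tuple):
                probes.extend([e[0], e[1]])
            else:
                probes.append(e)
        return probes

    @classmethod
    def _matches(cls, canon: str, entries: Iterable[str]) -> bool:
        root = canon[:3]
        for e in cls._parse(entries):
            if isinstance(e, tuple):
                if e[0] <= root <= e[1]:
                    return True
            elif len(e) == 3:
                if root == e:
                    return True
            elif canon.startswith(e):
                return True
        return False


DEFAULT_CODE_TABLE = CodeTable()


def classify_manner(
    ucod: str | None,
    codes: CodeTable = DEFAULT_CODE_TABLE,
    *,
    record_id: str | None = None,
) -> str:
    """Classify manner of death from an underlying cause-of-death code.

    Missing code -> ``"unknown"``; suicide ranges -> ``"suicide"``;
    undetermined-intent ranges -> ``"undetermined"``; anything else ->
    ``"other"``. Pure: depends only on ``(ucod, codes)``.
    """
    if ucod is None or (isinstance(ucod, float) and np.isnan(ucod)) or ucod is pd.NA:
        return "unknown"
    if isinstance(ucod, str) and not ucod.strip():
        return "unknown"
    canon = canonicalize_icd10(ucod, record_id=record_id)
    if CodeTable._matches(canon, codes.suicide):
        return "suicide"
    if CodeTable._matches(canon, codes.undetermined):
        return "undetermined"
    return "other"


def classify_manner_series(
    ucod: pd.Series, codes: CodeTable = DEFAULT_CODE_TABLE
) -> pd.Series:
    """Vectorized :func:`classify_manner` over a UCOD column."""
    cache: dict[object, str] = {}
    out = []
    for rid, code in zip(ucod.index, ucod.to_numpy(dtype=object)):
        key = code
        if key not in cache:
            cache[key] = classify_manner(code, codes, record_id=str(rid))
        out.append(cache[key])
    return pd.Series(out, index=ucod.index, dtype=object)


# ---------------------------------------------------------------------------
# field normalisation helpers

_SEX_MAP = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


def _norm_sex(value: object) -> object:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return pd.NA
    s = str(value).strip().lower()
    if not s:
        return pd.NA
    return _SEX_MAP.get(s, pd.NA)


def _norm_filn(value: object) -> object:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return pd.NA
    s = str(value).strip().upper()
    if not s:
        return pd.NA
    if len(s) != 1 or not s.isalpha():
        raise ValueError(f"invalid first initial {value!r}")
    return s


def _norm_ucod(value: object, record_id: str | None) -> object:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return pd.NA
    s = str(value).strip()
    if not s:
        return pd.NA
    return canonicalize_icd10(s, record_id=record_id)


def _norm_military(value: object) -> str:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("yes", "y", "1"):
        return "yes"
    if s in ("no", "n", "0"):
        return "no"
    return "unknown"


def _norm_manner(value: object) -> str:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("suicide", "intentional self-harm"):
        return "suicide"
    if s in ("undetermined", "undetermined intent"):
        return "undetermined"
    if not s:
        return "unknown"
    return "other"


def _col(df: pd.DataFrame, name: str) -> pd.Series:
    if name in df.columns:
        return df[name]
    return pd.Series(pd.NA, index=df.index, dtype=object)


def _require_columns(df: pd.DataFrame, required: Iterable[str], source: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source} table is missing required columns: {missing}")


def _mcod_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize the mcod1..mcod14 block, tolerating absent trailing columns."""
    out = {}
    for col in MCOD_COLUMNS:
        if col in raw.columns:
            vals = []
            for rid, v in zip(raw["record_id"], raw[col]):
                try:
                    vals.append(_norm_ucod(v, str(rid)))
                except ValueError as exc:
                    raise ValueError(f"malformed MCOD in column {col}: {exc}") from exc
            out[col] = pd.Series(vals, index=raw.index, dtype=object)
        else:
            out[col] = pd.Series(pd.NA, index=raw.index, dtype=object)
    return pd.DataFrame(out, index=raw.index)


# ---------------------------------------------------------------------------
# harmonization


def completed_years(dob: pd.Series, dod: pd.Series) -> pd.Series:
    """Age in completed calendar years (birthday rule) between two date columns."""
    before_birthday = (dod.dt.month * 100 + dod.dt.day) < (
        dob.dt.month * 100 + dob.dt.day
    )
    return (dod.dt.year - dob.dt.year - before_birthday.astype(int)).astype("Int64")


def harmonize_mdr(
    raw: pd.DataFrame, codes: CodeTable = DEFAULT_CODE_TABLE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a raw MDR extract.

    Derives ``dmb`` (day component of date of birth) and ``age_at_death``
    (completed years), classifies manner from the UCOD, and drops the date of
    birth. Returns ``(harmonized, rejects)``; rejects carry a ``reason``
    column (unparseable dates, death before birth).
    """
    _require_columns(
        raw, ["record_id", "state", "year", "date_of_birth", "death_date"], "MDR"
    )
    raw = raw.reset_index(drop=True)
    if raw["record_id"].duplicated().any():
        dup = raw.loc[raw["record_id"].duplicated(), "record_id"].iloc[0]
        raise SchemaError(f"duplicate MDR record_id {dup!r}")

    dob = pd.to_datetime(raw["date_of_birth"], errors="coerce", format="ISO8601")
    dod = pd.to_datetime(raw["death_date"], errors="coerce", format="ISO8601")

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[dob.isna()] = "unparseable or missing date_of_birth"
    reasons[dod.isna() & (reasons == "")] = "unparseable or missing death_date"
    ok = reasons == ""
    reasons[ok & (dod < dob)] = "death before birth"
    ok = reasons == ""

    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    kept = raw.loc[ok]
    out = pd.DataFrame(index=kept.index)
    out["record_id"] = kept["record_id"].astype(str)
    out["source"] = "MDR"
    out["state"] = kept["state"].astype(str).str.upper()
    out["year"] = pd.to_numeric(kept["year"]).astype(int)
    out["death_date"] = dod[ok]
    out["age_at_death"] = completed_years(dob[ok], dod[ok])
    out["sex"] = _col(kept, "sex").map(_norm_sex)
    out["dmb"] = dob[ok].dt.day.astype("Int64")
    out["filn"] = pd.Series(
        [_norm_filn(v) for v in _col(kept, "filn")], index=kept.index, dtype=object
    )
    out["ucod"] = [
        _norm_ucod(v, str(r)) for r, v in zip(kept["record_id"], _col(kept, "ucod"))
    ]
    mcod = _mcod_frame(kept)
    for col in MCOD_COLUMNS:
        out[col] = mcod[col]
    out["manner"] = classify_manner_series(out["ucod"], codes).to_numpy()
    out["military_history"] = pd.NA
    out["veteran_flag"] = True
    out = out[list(HARMONIZED_COLUMNS)].reset_index(drop=True)
    assert_no_dob(out)
    return out, rejects.reset_index(drop=True)


def harmonize_nvdrs(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a raw NVDRS extract into the shared schema.

    NVDRS supplies ``age_at_death`` and ``dmb`` directly (it never carries a
    full date of birth); manner comes from its own manner-of-death variable,
    and the military-history indicator is normalised to yes/no/unknown.
    """
    _require_columns(raw, ["record_id", "state", "year"], "NVDRS")
    raw = raw.reset_index(drop=True)
    if raw["record_id"].duplicated().any():
        dup = raw.loc[raw["record_id"].duplicated(), "record_id"].iloc[0]
        raise SchemaError(f"duplicate NVDRS record_id {dup!r}")

    dod = pd.to_datetime(_col(raw, "death_date").astype(object), errors="coerce", format="ISO8601")
    age = pd.to_numeric(_col(raw, "age_at_death"), errors="coerce").astype("Int64")
    dmb = pd.to_numeric(_col(raw, "dmb"), errors="coerce").astype("Int64")

    reasons = pd.Series("", index=raw.index, dtype=object)
    bad_dmb = dmb.notna() & ((dmb < 1) | (dmb > 31))
    reasons[bad_dmb.fillna(False)] = "day-of-month of birth outside 1-31"
    bad_age = age.notna() & (age < 0)
    reasons[bad_age.fillna(False) & (reasons == "")] = "negative age"
    ok = reasons == ""

    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    kept = raw.loc[ok]
    out = pd.DataFrame(index=kept.index)
    out["record_id"] = kept["record_id"].astype(str)
    out["source"] = "NVDRS"
    out["state"] = kept["state"].astype(str).str.upper()
    out["year"] = pd.to_numeric(kept["year"]).astype(int)
    out["death_date"] = dod[ok]
    out["age_at_death"] = age[ok]
    out["sex"] = _col(kept, "sex").map(_norm_sex)
    out["dmb"] = dmb[ok]
    out["filn"] = pd.Series(
        [_norm_filn(v) for v in _col(kept, "filn")], index=kept.index, dtype=object
    )
    out["ucod"] = [
        _norm_ucod(v, str(r)) for r, v in zip(kept["record_id"], _col(kept, "ucod"))
    ]
    mcod = _mcod_frame(kept)
    for col in MCOD_COLUMNS:
        out[col] = mcod[col]
    out["manner"] = _col(kept, "manner").map(_norm_manner)
    out["military_history"] = _col(kept, "military_history").map(_norm_military)
    out["veteran_flag"] = pd.NA
    out = out[list(HARMONIZED_COLUMNS)].reset_index(drop=True)
    assert_no_dob(out)
    return out, rejects.reset_index(drop=True)


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to suicide / undetermined-intent deaths aged >= 17 (or age missing).

    Idempotent and never increases the record count. Records with missing age
    stay eligible for linkage; age-stratified evaluation excludes them later.
    """
    manner_ok = records["manner"].isin(["suicide", "undetermined"])
    age = records["age_at_death"]
    age_ok = age.isna() | (age >= 17)
    return records.loc[manner_ok & age_ok].reset_index(drop=True)


def assert_no_dob(df: pd.DataFrame) -> None:
    """Schema scan: no artifact may retain a full date of birth."""
    banned = [c for c in df.columns if c.lower() in ("date_of_birth", "dob", "birth_date")]
    if banned:
        raise AssertionError(f"date of birth leaked into output columns: {banned}")


def mcod_set(row: pd.Series) -> frozenset[str]:
    """Present MCOD codes of a harmonized row, as a set of canonical codes."""
    return frozenset(
        v for v in (row[c] for c in MCOD_COLUMNS) if isinstance(v, str) and v
    )


# ---------------------------------------------------------------------------
# CSV I/O (delimited-text contract; mcod as 14 columns, empty = absent)


def read_registry_csv(
    path: str | Path, source: str, codes: CodeTable = DEFAULT_CODE_TABLE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and harmonize a raw registry CSV for the given source."""
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": pd.NA})
    if source == "MDR":
        return harmonize_mdr(raw, codes)
    return harmonize_nvdrs(raw)


def read_harmonized_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV previously written by :func:`write_harmonized_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": pd.NA})
    _require_columns(df, HARMONIZED_COLUMNS, "harmonized")
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    df["age_at_death"] = pd.to_numeric(df["age_at_death"], errors="coerce").astype(
        "Int64"
    )
    df["dmb"] = pd.to_numeric(df["dmb"], errors="coerce").astype("Int64")
    df["veteran_flag"] = df["veteran_flag"].map(
        {"True": True, "False": False, "true": True, "false": False}
    )
    return df


def write_harmonized_csv(df: pd.DataFrame, path: str | Path) -> None:
    assert_no_dob(df)
    out = df.copy()
    out["death_date"] = out["death_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")
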