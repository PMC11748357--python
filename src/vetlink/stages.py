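"""Declarative definitions of the seven linkage passes.

The linkage runs three stages (seven passes) of progressively relaxed
deterministic keys, always blocked within a state-year stratum:

* **S1** (*exact*): all six linkage variables — age, sex, UCOD, day-of-month
  of birth, first initial of last name, death date.
* **S2a–S2d** (*probable*): one variable dropped per pass, in order UCOD,
  DMB, FILN, death date.
* **S3a** (*possible*): DMB and FILN both dropped.
* **S3b** (*possible*): UCOD, DMB and FILN out of the key, and the NVDRS
  candidate pool restricted to records where DMB and FILN are both missing.

A record missing any key variable has no key for that pass and sits the pass
out; missingness is never a wildcard.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import LINKAGE_VARIABLES

#: fixed rendering order of key variables inside a concatenated key
KEY_ORDER = LINKAGE_VARIABLES

TIERS = ("exact", "probable", "possible")

_SEX_RENDER = {"male": "M", "female": "F"}
_DELIMITER = "|"


@dataclass(frozen=True)
class StageSpec:
    """One linkage pass: its key variables and candidate-pool restriction."""

    stage_id: str
    key_variables: tuple[str, ...]
    tier: str
    #: S3b only: restrict the NVDRS pool to records with DMB and FILN missing
    require_nvdrs_dmb_filn_missing: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.key_variables) - set(KEY_ORDER)
        if unknown:
            raise ValueError(f"unknown key variables {sorted(unknown)}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if not {"age_at_death", "sex"} <= set(self.key_variables):
            raise ValueError("age and sex must appear in every stage key")

    @property
    def relaxed_variables(self) -> tuple[str, ...]:
        """Linkage variables outside this pass's key (free to disagree)."""
        return tuple(v for v in KEY_ORDER if v not in self.key_variables)


def _spec(stage_id: str, dropped: tuple[str, ...], tier: str, **kw) -> StageSpec:
    keys = tuple(v for v in KEY_ORDER if v not in dropped)
    return StageSpec(stage_id=stage_id, key_variables=keys, tier=tier, **kw)


DEFAULT_STAGES: tuple[StageSpec, ...] = (
    _spec("S1", (), "exact"),
    _spec("S2a", ("ucod",), "probable"),
    _spec("S2b", ("dmb",), "probable"),
    _spec("S2c", ("filn",), "probable"),
    _spec("S2d", ("death_date",), "probable"),
    _spec("S3a", ("dmb", "filn"), "possible"),
    _spec(
        "S3b",
        ("ucod", "dmb", "filn"),
        "possible",
        require_nvdrs_dmb_filn_missing=True,
    ),
)

STAGES_BY_ID = {s.stage_id: s for s in DEFAULT_STAGES}


def stage_sequence(stage_ids: list[str] | None = None) -> tuple[StageSpec, ...]:
    """Resolve stage ids (case-insensitive) into specs; default is all seven."""
    if stage_ids is None:
        return DEFAULT_STAGES
    out = []
    for sid in stage_ids:
        key = sid.strip()
        key = key[:1].upper() + key[1:].lower()
        if key not in STAGES_BY_ID:
            raise ValueError(f"unknown stage id {sid!r}")
        out.append(STAGES_BY_ID[key])
    return tuple(out)


def render_value(variable: str, value) -> str | None:
    """Canonical string rendering of one key variable, or None when missing."""
    if value is None or value is pd.NA or pd.isna(value):
        return None
    if variable == "age_at_death":
        return str(int(value))
    if variable == "sex":
        return _SEX_RENDER.get(value)
    if variable == "dmb":
        return str(int(value))
    if variable == "death_date":
        return pd.Timestamp(value).strftime("%Y-%m-%d")
    return str(value)


def build_stage_key(record, spec: StageSpec) -> str | None:
    """Concatenated key for one record, or None if any key variable is missing."""
    parts = []
    for var in KEY_ORDER:
        if var not in spec.key_variables:
            continue
        rendered = render_value(var, record[var])
        if rendered is None:
            return None
        parts.append(rendered)
    return _DELIMITER.join(parts)


def stage_keys(df: pd.DataFrame, spec: StageSpec) -> pd.Series:
    """Vectorized :func:`build_stage_key` over a harmonized table.

    Returns a string Series aligned to ``df`` with ``NA`` where any key
    variable is missing. Keys are prefixed with the state-year stratum so a
    join on the key can never leak a match across strata.
    """
    rendered: list[pd.Series] = [
        df["state"].astype(str),
        df["year"].astype(int).astype(str),
    ]
    for var in KEY_ORDER:
        if var not in spec.key_variables:
            continue
        col = df[var]
        if var == "age_at_death" or var == "dmb":
            s = col.astype("Int64").astype(str).where(col.notna())
        elif var == "sex":
            s = col.map(_SEX_RENDER)
        elif var == "death_date":
            s = col.dt.strftime("%Y-%m-%d")
        else:
            s = col.astype(object).where(col.notna())
        rendered.append(s)
    key = rendered[0].str.cat(rendered[1:], sep=_DELIMITER)
    return key
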