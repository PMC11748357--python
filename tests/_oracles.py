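"""Independent brute-force oracles the engine tests compare against.

Deliberately free of the package's key machinery: field-by-field comparison
over all record pairs, and a calendar-walking age computation.
"""

from datetime import date, timedelta

import pandas as pd


def brute_force_age(dob: date, dod: date) -> int:
    """Completed years by walking the calendar one birthday at a time."""
    years = 0
    while True:
        try:
            birthday = date(dob.year + years + 1, dob.month, dob.day)
        except ValueError:  # Feb 29 in a common year
            birthday = date(dob.year + years + 1, 3, 1)
        if birthday > dod:
            return years
        years += 1


def _pair_compatible(m: pd.Series, n: pd.Series, spec) -> bool:
    if m["state"] != n["state"] or int(m["year"]) != int(n["year"]):
        return False
    if spec.require_nvdrs_dmb_filn_missing and not (
        pd.isna(n["dmb"]) and pd.isna(n["filn"])
    ):
        return False
    for var in spec.key_variables:
        a, b = m[var], n[var]
        if pd.isna(a) or pd.isna(b):
            return False
        if a != b:
            return False
    return True


def brute_force_pass(mdr: pd.DataFrame, nvdrs: pd.DataFrame, spec):
    """All-pairs comparison for one pass.

    Returns (unique_matches, ambiguous_ids): the set of (mdr_id, nvdrs_id)
    pairs where neither side has any other compatible partner, and the ids of
    records involved in multi-way compatibility (duplicate groups).
    """
    m_rows = list(mdr.iterrows())
    n_rows = list(nvdrs.iterrows())
    compat = {}
    for _, m in m_rows:
        for _, n in n_rows:
            if _pair_compatible(m, n, spec):
                compat.setdefault(m["record_id"], set()).add(n["record_id"])

    partners_of_n = {}
    for m_id, n_ids in compat.items():
        for n_id in n_ids:
            partners_of_n.setdefault(n_id, set()).add(m_id)

    unique = set()
    ambiguous = set()
    for m_id, n_ids in compat.items():
        if len(n_ids) == 1:
            n_id = next(iter(n_ids))
            if len(partners_of_n[n_id]) == 1:
                unique.add((m_id, n_id))
                continue
        ambiguous.add(m_id)
        ambiguous.update(n_ids)
    for n_id, m_ids in partners_of_n.items():
        if len(m_ids) > 1:
            ambiguous.add(n_id)
            ambiguous.update(m_ids)
    return unique, ambiguous
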