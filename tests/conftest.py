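import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vetlink.records import HARMONIZED_COLUMNS, MCOD_COLUMNS


def make_record(**kw):
    """One harmonized row with sensible defaults, as a dict."""
    base = {
        "record_id": "R1",
        "source": "NVDRS",
        "state": "GA",
        "year": 2015,
        "death_date": pd.Timestamp("2015-03-14"),
        "age_at_death": 64,
        "sex": "male",
        "dmb": 15,
        "filn": "K",
        "ucod": "X70",
        **{c: pd.NA for c in MCOD_COLUMNS},
        "manner": "suicide",
        "military_history": "unknown",
        "veteran_flag": pd.NA,
    }
    base.update(kw)
    return base


def make_table(rows):
    df = pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))
    df["death_date"] = pd.to_datetime(df["death_date"])
    df["age_at_death"] = df["age_at_death"].astype("Int64")
    df["dmb"] = df["dmb"].astype("Int64")
    df["year"] = df["year"].astype(int)
    return df


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def table_factory():
    return make_table
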