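"""Linkage-success metrics: rates, strata profiles, concordance, missingness."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vetlink.engine import run_linkage
from vetlink.evaluate import (
    concordance_report,
    match_rate,
    percent,
    profile_missingness,
    profile_strata,
    round_half_up,
    stage_breakdown,
    state_year_rates,
)
from vetlink.records import LINKAGE_VARIABLES, filter_eligible
from vetlink.simulate import default_study_config, simulate

from .conftest import make_record, make_table


class TestMatchRate:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (22019, 24685, 89.20),
            (70, 89, 78.65),
            (0, 100, 0.00),
            (1, 3, 33.33),
            (1, 800, 0.13),  # 0.125 rounds half-up
        ],
    )
    def test_values(self, k, n, expected):
        assert match_rate(k, n) == expected

    def test_zero_denominator_is_not_applicable(self):
        assert match_rate(0, 0) is None

    @given(k=st.integers(0, 1000), n=st.integers(1, 1000), scale=st.integers(1, 9))
    def test_scale_invariance(self, k, n, scale):
        k = min(k, n)
        assert match_rate(k, n) == match_rate(k * scale, n * scale)

    def test_half_up_rounding_convention(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.124999, 2) == 0.12
        assert percent(1, 8) == 12.50


class TestProfileStrata:
    def _table(self, rows):
        return make_table(rows)

    def test_high_missingness_stratum_incomplete(self):
        rows = []
        for i in range(100):
            missing = i < 12  # 12% of records miss dmb and filn
            rows.append(
                make_record(
                    record_id=f"N{i}",
                    dmb=pd.NA if missing else 5,
                    filn=pd.NA if missing else "K",
                )
            )
        profiles = profile_strata(self._table(rows))
        assert not profiles.iloc[0]["complete"]
        assert profiles.iloc[0]["prop_missing_2plus"] == 0.12

    def test_partial_reporting_stratum_incomplete_despite_clean_data(self):
        rows = [make_record(record_id=f"N{i}") for i in range(50)]
        profiles = profile_strata(self._table(rows), partial_reporting=[("GA", 2015)])
        assert not profiles.iloc[0]["complete"]
        assert profiles.iloc[0]["partial_reporting"]

    def test_clean_full_reporting_stratum_complete(self):
        rows = [make_record(record_id=f"N{i}") for i in range(50)]
        profiles = profile_strata(self._table(rows))
        assert profiles.iloc[0]["complete"]

    def test_exactly_at_threshold_is_complete_and_flagged(self):
        # strictly-greater-than comparison: 10.0% exactly stays complete
        rows = []
        for i in range(100):
            missing = i < 10
            rows.append(
                make_record(
                    record_id=f"N{i}",
                    dmb=pd.NA if missing else 5,
                    filn=pd.NA if missing else "K",
                )
            )
        profiles = profile_strata(self._table(rows))
        assert profiles.iloc[0]["complete"]
        assert profiles.iloc[0]["at_threshold"]

    def test_empty_stratum_incomplete(self):
        rows = [make_record(record_id="N0", state="GA")]
        profiles = profile_strata(
            self._table(rows), partial_reporting=[("TX", 2013)]
        )
        tx = profiles[(profiles["state"] == "TX")].iloc[0]
        assert tx["n_nvdrs_records"] == 0 and not tx["complete"]


@pytest.fixture(scope="module")
def study_linkage():
    cfg = default_study_config(seed=19)
    cfg.decedents_per_stratum = 250
    r = simulate(cfg)
    mdr = filter_eligible(r.mdr)
    nvdrs = filter_eligible(r.nvdrs)
    result = run_linkage(mdr, nvdrs)
    profiles = profile_strata(nvdrs, cfg.partial_strata())
    return cfg, mdr, nvdrs, result, profiles


class TestStageBreakdown:
    def test_tiers_sum_to_100_within_rounding(self, study_linkage):
        _, mdr, _, result, profiles = study_linkage
        for restrict in (False, True):
            out = stage_breakdown(result, mdr, profiles, restrict).set_index("tier")
            total = (
                out.loc["exact", "pct_of_mdr"]
                + out.loc["probable", "pct_of_mdr"]
                + out.loc["possible", "pct_of_mdr"]
                + out.loc["unmatched", "pct_of_mdr"]
            )
            assert abs(total - 100.0) <= 0.02

    def test_tier_shares_match_audit_recount(self, study_linkage):
        _, mdr, _, result, profiles = study_linkage
        out = stage_breakdown(result, mdr).set_index("tier")
        recount = result.matches.groupby("tier").size()
        for tier in ("exact", "probable", "possible"):
            assert out.loc[tier, "n_matched"] == recount.get(tier, 0)
            assert out.loc[tier, "pct_of_mdr"] == percent(
                int(recount.get(tier, 0)), len(mdr)
            )

    def test_no_matches_gives_zero_tiers(self, study_linkage):
        _, mdr, nvdrs, _, _ = study_linkage
        empty = run_linkage(mdr.iloc[0:0], nvdrs.iloc[0:0])
        out = stage_breakdown(empty, mdr).set_index("tier")
        assert out.loc["exact", "pct_of_mdr"] == 0.00
        assert out.loc["unmatched", "pct_of_mdr"] == 100.00

    def test_complete_restriction_never_lowers_quality(self, study_linkage):
        # mean per-variable NVDRS missingness among complete strata must not
        # exceed the overall mean (the filter exists to drop bad strata)
        _, _, nvdrs, _, profiles = study_linkage
        miss_cols = [f"prop_missing_{v}" for v in LINKAGE_VARIABLES]
        weights = profiles["n_nvdrs_records"]
        overall = (profiles[miss_cols].mul(weights, axis=0)).sum().sum() / weights.sum()
        comp = profiles[profiles["complete"]]
        w = comp["n_nvdrs_records"]
        complete_mean = (comp[miss_cols].mul(w, axis=0)).sum().sum() / w.sum()
        assert complete_mean <= overall


class TestConcordance:
    def test_buckets_equal_brute_force_recount(self, study_linkage):
        _, mdr, nvdrs, result, _ = study_linkage
        report = concordance_report(result, mdr, nvdrs)
        m_idx = mdr.set_index("record_id")
        n_idx = nvdrs.set_index("record_id")
        for stage_id, var in (("S2a", "ucod"), ("S3b", "ucod")):
            pairs = result.matches[result.matches["stage_id"] == stage_id]
            missing = different = 0
            for m_id, n_id in zip(pairs["mdr_record_id"], pairs["nvdrs_record_id"]):
                nv = n_idx.loc[n_id, var]
                if pd.isna(nv):
                    missing += 1
                elif nv != m_idx.loc[m_id, var]:
                    different += 1
            sel = report[(report["stage_id"] == stage_id)].set_index("bucket")
            assert sel.loc["nvdrs_ucod_missing", "n"] == missing
            assert sel.loc["ucod_different", "n"] == different

    def test_s2d_window_is_inclusive(self):
        mdr = make_table(
            [make_record(record_id="M1", source="MDR", death_date="2015-01-01")]
        )
        nvdrs = make_table([make_record(record_id="N1", death_date="2015-01-31")])
        result = run_linkage(mdr, nvdrs)
        assert list(result.matches["stage_id"]) == ["S2d"]
        report = concordance_report(result, mdr, nvdrs)
        sel = report[report["stage_id"] == "S2d"].set_index("bucket")
        assert sel.loc["within_30_days", "n"] == 1  # delta = 30 counts as within
        assert sel.loc["beyond_30_days", "n"] == 0

    def test_missing_date_share(self):
        rows_m, rows_n = [], []
        for i in range(10):
            rows_m.append(
                make_record(record_id=f"M{i}", source="MDR", filn=chr(65 + i))
            )
            rows_n.append(
                make_record(
                    record_id=f"N{i}",
                    filn=chr(65 + i),
                    death_date=pd.NaT if i < 9 else "2015-06-01",
                )
            )
        result = run_linkage(make_table(rows_m), make_table(rows_n))
        report = concordance_report(result, make_table(rows_m), make_table(rows_n))
        sel = report[report["stage_id"] == "S2d"].set_index("bucket")
        assert sel.loc["nvdrs_date_missing", "pct_of_pairs"] == 90.00


class TestMissingnessProfile:
    def test_counts_and_percentages(self):
        rows = [
            make_record(record_id=f"N{i}", ucod=pd.NA if i < 3 else "X70")
            for i in range(16)
        ]
        out = profile_missingness(make_table(rows))
        ucod = out[(out["variable"] == "ucod")].iloc[0]
        assert ucod["n_missing"] == 3
        assert ucod["pct_missing"] == 18.75

    def test_zero_missing(self):
        rows = [make_record(record_id=f"N{i}") for i in range(5)]
        out = profile_missingness(make_table(rows))
        assert (out["pct_missing"] == 0.00).all()


def test_state_year_rates_cover_every_stratum(study_linkage):
    _, mdr, _, result, _ = study_linkage
    rates = state_year_rates(result, mdr)
    assert len(rates) == len(mdr.groupby(["state", "year"]))
    assert (rates["n_linked"] <= rates["n_mdr"]).all()
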