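"""Military-history indicator validity: counts, metrics, confidence intervals."""

import numpy as np
import pandas as pd
import pytest

from vetlink.engine import run_linkage
from vetlink.evaluate import profile_strata
from vetlink.records import filter_eligible
from vetlink.simulate import noise_free_config, simulate
from vetlink.validity import (
    ValidityTable,
    age_band,
    build_validity_tables,
    metrics_from_table,
    wilson_interval,
)


def _table(**kw):
    base = dict(
        manner="suicide",
        sex="all",
        age_band="all",
        n_mdr_veterans=0,
        n_linked_yes=0,
        n_linked_no=0,
        n_linked_unknown=0,
        n_unlinked_yes=0,
        n_unlinked_no=0,
        n_unlinked_unknown=0,
    )
    base.update(kw)
    return ValidityTable(**base)


class TestMetricArithmetic:
    def test_sensitivity(self):
        t = _table(n_mdr_veterans=100, n_linked_yes=85)
        assert metrics_from_table(t)["sensitivity"]["estimate"] == 85.00

    def test_ppv(self):
        t = _table(n_linked_yes=40, n_unlinked_yes=10)
        assert metrics_from_table(t)["ppv"]["estimate"] == 80.00

    def test_accuracy_and_specificity(self):
        t = _table(
            n_mdr_veterans=60,
            n_linked_yes=50,
            n_linked_no=5,
            n_linked_unknown=5,
            n_unlinked_yes=10,
            n_unlinked_no=120,
            n_unlinked_unknown=10,
        )
        m = metrics_from_table(t)
        assert m["accuracy"]["estimate"] == 85.00  # (50+120)/200
        assert m["specificity"]["estimate"] == round(100 * 120 / 140, 2)
        assert m["npv"]["estimate"] == 96.00  # 120/125

    def test_zero_denominator_is_none_never_zero(self):
        m = metrics_from_table(_table())
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert m[name]["estimate"] is None


class TestWilsonInterval:
    def test_frozen_closed_form_value(self):
        lo, hi = wilson_interval(50, 100)
        assert (round(lo, 4), round(hi, 4)) == (0.4038, 0.5962)

    def test_closed_form_agreement(self):
        # independent closed-form evaluation of the score interval
        z = 1.959963984540054
        for k, n in ((5, 40), (50, 100), (190, 200)):
            p = k / n
            denom = 1 + z**2 / n
            center = (p + z**2 / (2 * n)) / denom
            hw = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
            lo, hi = wilson_interval(k, n)
            assert lo == pytest.approx(center - hw, abs=1e-10)
            assert hi == pytest.approx(center + hw, abs=1e-10)

    def test_ci_brackets_estimate_and_narrows_with_n(self):
        t_small = _table(n_mdr_veterans=50, n_linked_yes=40)
        t_big = _table(n_mdr_veterans=5000, n_linked_yes=4000)
        for t in (t_small, t_big):
            m = metrics_from_table(t)["sensitivity"]
            assert m["ci_low"] <= m["estimate"] <= m["ci_high"]
        width = lambda m: m["ci_high"] - m["ci_low"]
        assert width(metrics_from_table(t_big)["sensitivity"]) < width(
            metrics_from_table(t_small)["sensitivity"]
        )

    def test_clopper_pearson_is_wider(self):
        t = _table(n_mdr_veterans=100, n_linked_yes=85)
        w = metrics_from_table(t, "wilson")["sensitivity"]
        cp = metrics_from_table(t, "clopper-pearson")["sensitivity"]
        assert cp["ci_low"] <= w["ci_low"] and cp["ci_high"] >= w["ci_high"]


def test_age_bands():
    assert age_band(17) == "17-39"
    assert age_band(39) == "17-39"
    assert age_band(40) == "40-64"
    assert age_band(64) == "40-64"
    assert age_band(65) == "65+"
    assert age_band(95) == "65+"
    assert age_band(pd.NA) is None
    assert age_band(16) is None


@pytest.fixture(scope="module")
def perfect_indicator_run():
    """Noise-free run whose indicator equals Veteran status exactly."""
    cfg = noise_free_config(n_per_stratum=120, seed=29)
    cfg.indicator_model = {
        "p_unknown": 0.0,
        "p_yes_veteran": {
            s: {b: 1.0 for b in ("17-39", "40-64", "65+")} for s in ("male", "female")
        },
        "p_yes_nonveteran": {
            s: {b: 0.0 for b in ("17-39", "40-64", "65+")} for s in ("male", "female")
        },
    }
    r = simulate(cfg)
    mdr = filter_eligible(r.mdr)
    nvdrs = filter_eligible(r.nvdrs)
    result = run_linkage(mdr, nvdrs)
    profiles = profile_strata(nvdrs, cfg.partial_strata())
    tables = build_validity_tables(result, mdr, nvdrs, profiles)
    return r, mdr, nvdrs, result, tables


class TestBuildValidityTables:
    def test_perfect_indicator_gives_100_everywhere(self, perfect_indicator_run):
        _, _, _, _, tables = perfect_indicator_run
        populated = tables[tables["n_mdr_veterans"] > 0]
        assert (populated["sensitivity_pct"] == 100.00).all()
        assert (populated["accuracy_pct"] == 100.00).all()
        assert (populated["specificity_pct"] == 100.00).all()

    def test_bookkeeping_identity(self, perfect_indicator_run):
        # all NVDRS cells partition the scoped NVDRS table
        _, _, nvdrs, _, tables = perfect_indicator_run
        overall = tables[
            (tables["manner"] == "all")
            & (tables["sex"] == "all")
            & (tables["age_band"] == "all")
        ].iloc[0]
        cells = (
            overall["n_linked_yes"]
            + overall["n_linked_no"]
            + overall["n_linked_unknown"]
            + overall["n_unlinked_yes"]
            + overall["n_unlinked_no"]
            + overall["n_unlinked_unknown"]
        )
        assert cells == len(nvdrs)  # noise-free config: every stratum complete

    def test_accuracy_equals_record_by_record_agreement(self, perfect_indicator_run):
        r, _, nvdrs, result, tables = perfect_indicator_run
        linked = set(result.matches["nvdrs_record_id"])
        agree = 0
        for _, row in nvdrs.iterrows():
            is_vet = row["record_id"] in linked
            if is_vet and row["military_history"] == "yes":
                agree += 1
            elif not is_vet and row["military_history"] == "no":
                agree += 1
        overall = tables[
            (tables["manner"] == "all")
            & (tables["sex"] == "all")
            & (tables["age_band"] == "all")
        ].iloc[0]
        expected = round(100 * agree / len(nvdrs), 2)
        assert overall["accuracy_pct"] == expected

    def test_sensitivity_recovers_configured_indicator_rate(self):
        cfg = noise_free_config(n_per_stratum=400, seed=37)
        p_yes = 0.85
        cfg.indicator_model = {
            "p_unknown": 0.0,
            "p_yes_veteran": {
                s: {b: p_yes for b in ("17-39", "40-64", "65+")}
                for s in ("male", "female")
            },
            "p_yes_nonveteran": {
                s: {b: 0.03 for b in ("17-39", "40-64", "65+")}
                for s in ("male", "female")
            },
        }
        r = simulate(cfg)
        mdr = filter_eligible(r.mdr)
        nvdrs = filter_eligible(r.nvdrs)
        result = run_linkage(mdr, nvdrs)
        profiles = profile_strata(nvdrs, cfg.partial_strata())
        tables = build_validity_tables(result, mdr, nvdrs, profiles)
        overall = tables[
            (tables["manner"] == "all")
            & (tables["sex"] == "all")
            & (tables["age_band"] == "all")
        ].iloc[0]
        assert overall["sensitivity_ci_low"] <= 100 * p_yes <= overall["sensitivity_ci_high"]

    def test_metrics_bounded(self, perfect_indicator_run):
        _, _, _, _, tables = perfect_indicator_run
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            vals = tables[f"{name}_pct"].dropna()
            assert ((vals >= 0) & (vals <= 100)).all()
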