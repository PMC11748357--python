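"""Synthetic dual-registry generator with ground-truth links.

Draws a universe of suicide / undetermined-intent decedents over state-year
strata, then emits:

* an MDR-like table — every Veteran decedent, minus a configurable
  under-coverage fraction (higher for the oldest band, mirroring incomplete
  electronic personnel records for older Veterans);
* an NVDRS-like table — every decedent retained with the stratum's reporting
  fraction (1.0 = full reporting), with field discrepancies and per-variable
  missingness injected, plus a military-history indicator drawn from a
  sex- and age-dependent error model;
* a truth table of the one-to-one MDR-NVDRS links actually present in both
  outputs.

Both tables come out in the harmonized schema of :mod:`vetlink.records`, so
the generator's output feeds the linkage engine directly. The same seed and
configuration always produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import HARMONIZED_COLUMNS, MCOD_COLUMNS, assert_no_dob, write_harmonized_csv
from .stages import DEFAULT_STAGES, stage_keys

SEX_LEVELS = ("male", "female")
BAND_LEVELS = ("17-39", "40-64", "65+")
_BAND_RANGES = {"17-39": (17, 39), "40-64": (40, 64), "65+": (65, 94)}

# approximate frequencies of US surname initials; collisions on FILN within a
# stratum are the natural source of duplicate groups
_FILN_LETTERS = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
_FILN_WEIGHTS = np.array(
    [
        0.0705, 0.0860, 0.0744, 0.0494, 0.0217, 0.0352, 0.0567, 0.0744,
        0.0082, 0.0294, 0.0390, 0.0466, 0.0905, 0.0272, 0.0156, 0.0599,
        0.0038, 0.0547, 0.0933, 0.0403, 0.0020, 0.0196, 0.0596, 0.0005,
        0.0123, 0.0092,
    ]
)
_FILN_WEIGHTS = _FILN_WEIGHTS / _FILN_WEIGHTS.sum()

# modest UCOD pools per manner (all inside the default classification ranges);
# weights loosely follow the national method mix
_SUICIDE_UCOD = np.array(["X70", "X72", "X73", "X74", "X60", "X63", "X78", "X80", "X84"])
_SUICIDE_W = np.array([0.27, 0.25, 0.10, 0.15, 0.05, 0.04, 0.05, 0.04, 0.05])
_UNDET_UCOD = np.array(["Y10", "Y12", "Y14", "Y21", "Y24", "Y30", "Y33"])
_UNDET_W = np.array([0.18, 0.22, 0.25, 0.10, 0.10, 0.08, 0.07])

# nature-of-injury / contributing-cause codes for the MCOD block
_MCOD_EXTRA = np.array(
    ["T71", "T360", "T402", "T424", "T509", "T58", "T659", "R99", "S099", "T140"]
)
# circumstance codes NVDRS abstractors sometimes add beyond the certificate
_NVDRS_ONLY_MCOD = np.array(["F102", "F329", "R458", "Z915"])


def _as_prob(name: str, value: float) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return v


@dataclass
class SimulationConfig:
    """All generative quantities of one synthetic study.

    Probabilities are unconditional marginals. ``indicator_model`` maps sex
    and age band to P(indicator = yes) separately for Veterans and
    non-Veterans, with a flat P(unknown); the configured Veteran
    yes-probability is therefore exactly the sensitivity analogue the
    validity module should recover.
    """

    states: tuple[str, ...]
    years: tuple[int, ...]
    decedents_per_stratum: int
    seed: int = 0
    veteran_fraction: float = 0.13
    suicide_fraction: float = 0.87
    #: P(male) by Veteran status
    sex_mix: dict = field(
        default_factory=lambda: {"veteran": 0.95, "non_veteran": 0.75}
    )
    age_distribution: dict = field(
        default_factory=lambda: {"17-39": 0.36, "40-64": 0.46, "65+": 0.18}
    )
    #: per-source, per-variable missingness probabilities
    missingness: dict = field(
        default_factory=lambda: {
            "NVDRS": {
                "ucod": 0.0,
                "death_date": 0.0,
                "dmb": 0.0,
                "filn": 0.0,
                "age_at_death": 0.0,
                "sex": 0.0,
            },
            "MDR": {"dmb": 0.0, "filn": 0.0},
        }
    )
    #: per-state overrides of NVDRS missingness, e.g. {"CO": {"dmb": 0.55}}
    missingness_overrides: dict = field(default_factory=dict)
    #: couple dmb/filn missingness comonotonically (states reporting neither)
    correlated_dmb_filn: bool = False
    discrepancy_rates: dict = field(
        default_factory=lambda: {
            "death_date": 0.0,  # small shifts, 1-30 days
            "death_date_large": 0.0,  # rare shifts, 31-364 days
            "ucod": 0.0,  # recode within manner
            "dmb": 0.0,
            "filn": 0.0,
            "mcod_drop": 0.0,  # MDR-certificate code absent from NVDRS
            "mcod_extra": 0.0,  # NVDRS-only circumstance code appended
        }
    )
    indicator_model: dict = field(
        default_factory=lambda: {
            "p_unknown": 0.05,
            "p_yes_veteran": {
                "male": {"17-39": 0.79, "40-64": 0.88, "65+": 0.94},
                "female": {"17-39": 0.50, "40-64": 0.63, "65+": 0.75},
            },
            "p_yes_nonveteran": {
                "male": {"17-39": 0.040, "40-64": 0.045, "65+": 0.050},
                "female": {"17-39": 0.006, "40-64": 0.008, "65+": 0.010},
            },
        }
    )
    #: per-state NVDRS sampling fraction, e.g. {"PA": {"2016": 0.8}} or {"PA": 0.8}
    partial_reporting: dict = field(default_factory=dict)
    mdr_undercoverage: dict = field(
        default_factory=lambda: {"default": 0.0, "65+": 0.0}
    )
    #: perturb colliding records until every decedent's full six-variable key
    #: is unique within its stratum (guarantees noise-free stage-1 recovery)
    ensure_unique_keys: bool = False

    def __post_init__(self) -> None:
        if not self.states or not self.years:
            raise ValueError("states and years must be non-empty")
        self.states = tuple(str(s).upper() for s in self.states)
        self.years = tuple(int(y) for y in self.years)
        if int(self.decedents_per_stratum) < 0:
            raise ValueError("decedents_per_stratum must be >= 0")
        _as_prob("veteran_fraction", self.veteran_fraction)
        _as_prob("suicide_fraction", self.suicide_fraction)
        for k, v in self.sex_mix.items():
            _as_prob(f"sex_mix[{k}]", v)
        w = [self.age_distribution[b] for b in BAND_LEVELS]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("age_distribution weights must be >= 0 and sum to 1")
        for src, d in self.missingness.items():
            for k, v in d.items():
                _as_prob(f"missingness[{src}][{k}]", v)
        for st, d in self.missingness_overrides.items():
            for k, v in d.items():
                _as_prob(f"missingness_overrides[{st}][{k}]", v)
        for k, v in self.discrepancy_rates.items():
            _as_prob(f"discrepancy_rates[{k}]", v)
        _as_prob("p_unknown", self.indicator_model["p_unknown"])
        for grp in ("p_yes_veteran", "p_yes_nonveteran"):
            for sex in SEX_LEVELS:
                for band in BAND_LEVELS:
                    p = _as_prob(
                        f"indicator_model[{grp}][{sex}][{band}]",
                        self.indicator_model[grp][sex][band],
                    )
                    if p + self.indicator_model["p_unknown"] > 1.0:
                        raise ValueError("P(yes) + P(unknown) exceeds 1")
        for st, v in self.partial_reporting.items():
            if isinstance(v, dict):
                for y, f in v.items():
                    _as_prob(f"partial_reporting[{st}][{y}]", f)
            else:
                _as_prob(f"partial_reporting[{st}]", v)
        for k, v in self.mdr_undercoverage.items():
            _as_prob(f"mdr_undercoverage[{k}]", v)

    # -- config plumbing ----------------------------------------------------

    def reporting_fraction(self, state: str, year: int) -> float:
        v = self.partial_reporting.get(state)
        if v is None:
            return 1.0
        if isinstance(v, dict):
            return float(v.get(str(year), v.get(year, 1.0)))
        return float(v)

    def nvdrs_missingness(self, state: str) -> dict:
        base = dict(self.missingness.get("NVDRS", {}))
        base.update(self.missingness_overrides.get(state, {}))
        return base

    def partial_strata(self) -> list[tuple[str, int]]:
        """Strata with a reporting fraction below 1 (for completeness filters)."""
        return [
            (s, y)
            for s in self.states
            for y in self.years
            if self.reporting_fraction(s, y) < 1.0
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["states"] = list(self.states)
        d["years"] = list(self.years)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The study conditions the generator emulates by default.

    Eight states over 2012-2018 at 900 decedents per stratum (~50,000
    NVDRS-like records). NVDRS missingness: UCOD 5.44%, death date 4.26%,
    DMB 12%, FILN 10%, age/sex well under 1%; MDR missingness at most 0.25%
    per variable. One chronically high-missingness state (CO) and one
    partial-reporting state (PA, 80% from 2016). Veteran fraction 0.13;
    indicator yes-marginals ≈0.86 for male and ≈0.62 for female Veterans.
    """
    return SimulationConfig(
        states=("AZ", "CO", "GA", "KY", "MA", "NJ", "OR", "PA"),
        years=tuple(range(2012, 2019)),
        decedents_per_stratum=900,
        seed=seed,
        veteran_fraction=0.13,
        suicide_fraction=0.87,
        missingness={
            "NVDRS": {
                "ucod": 0.0544,
                "death_date": 0.0426,
                "dmb": 0.12,
                "filn": 0.10,
                "age_at_death": 0.003,
                "sex": 0.0002,
            },
            "MDR": {"dmb": 0.0024, "filn": 0.0024},
        },
        missingness_overrides={"CO": {"dmb": 0.55, "filn": 0.50}},
        correlated_dmb_filn=False,
        discrepancy_rates={
            "death_date": 0.008,
            "death_date_large": 0.002,
            "ucod": 0.010,
            "dmb": 0.005,
            "filn": 0.005,
            "mcod_drop": 0.05,
            "mcod_extra": 0.30,
        },
        partial_reporting={"PA": {"2016": 0.8, "2017": 0.8, "2018": 0.8}},
        mdr_undercoverage={"default": 0.03, "65+": 0.08},
    )


def noise_free_config(
    n_per_stratum: int = 200, seed: int = 0, **overrides
) -> SimulationConfig:
    """A noise-free limit of the study config: no missingness, no
    discrepancies, full reporting, no under-coverage, unique stage-1 keys.

    Every MDR record then has an NVDRS partner agreeing on all six linkage
    variables, so stage 1 must recover the truth file exactly.
    """
    cfg = default_study_config(seed=seed)
    cfg.decedents_per_stratum = n_per_stratum
    cfg.missingness = {
        "NVDRS": {v: 0.0 for v in cfg.missingness["NVDRS"]},
        "MDR": {v: 0.0 for v in cfg.missingness["MDR"]},
    }
    cfg.missingness_overrides = {}
    cfg.discrepancy_rates = {k: 0.0 for k in cfg.discrepancy_rates}
    cfg.partial_reporting = {}
    cfg.mdr_undercoverage = {"default": 0.0, "65+": 0.0}
    cfg.ensure_unique_keys = True
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SimulationResult:
    mdr: pd.DataFrame
    nvdrs: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _choice(rng, values, weights, size):
    idx = rng.choice(len(values), size=size, p=weights)
    return np.asarray(values)[idx]


def _recode_within_pool(rng, codes, pool):
    """Replace each code with a different one from the same pool."""
    pool_index = {c: i for i, c in enumerate(pool)}
    idx = np.array([pool_index[c] for c in codes])
    shift = rng.integers(1, len(pool), size=len(codes))
    return np.asarray(pool)[(idx + shift) % len(pool)]


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> SimulationResult:
    """Generate the decedent universe and both registries.

    ``seed`` overrides ``config.seed`` when given. Deterministic: the same
    (config, seed) always yields identical tables.
    """
    rng = np.random.default_rng(config.seed if seed is None else int(seed))

    strata = [(s, y) for s in config.states for y in config.years]
    n_per = int(config.decedents_per_stratum)
    n_total = n_per * len(strata)

    state = np.repeat([s for s, _ in strata], n_per)
    year = np.repeat([y for _, y in strata], n_per)

    vet = rng.random(n_total) < config.veteran_fraction
    manner = np.where(
        rng.random(n_total) < config.suicide_fraction, "suicide", "undetermined"
    )
    p_male = np.where(
        vet, config.sex_mix["veteran"], config.sex_mix["non_veteran"]
    )
    sex = np.where(rng.random(n_total) < p_male, "male", "female")

    band_idx = rng.choice(
        len(BAND_LEVELS),
        size=n_total,
        p=[config.age_distribution[b] for b in BAND_LEVELS],
    )
    band = np.asarray(BAND_LEVELS)[band_idx]
    lo = np.array([_BAND_RANGES[b][0] for b in band])
    hi = np.array([_BAND_RANGES[b][1] for b in band])
    age = rng.integers(lo, hi + 1)

    doy = rng.integers(0, 365, size=n_total)
    death_date = pd.to_datetime(
        pd.DataFrame({"year": year, "month": 1, "day": 1})
    ) + pd.to_timedelta(doy, unit="D")
    dmb = rng.integers(1, 29, size=n_total)
    filn = _choice(rng, _FILN_LETTERS, _FILN_WEIGHTS, n_total)

    ucod = np.empty(n_total, dtype=object)
    su = manner == "suicide"
    ucod[su] = _choice(rng, _SUICIDE_UCOD, _SUICIDE_W / _SUICIDE_W.sum(), int(su.sum()))
    ucod[~su] = _choice(rng, _UNDET_UCOD, _UNDET_W / _UNDET_W.sum(), int((~su).sum()))

    # MCOD: the UCOD plus 1-3 contributing-cause codes
    n_extra = rng.integers(1, 4, size=n_total)
    e1 = rng.integers(0, len(_MCOD_EXTRA), size=n_total)
    e2 = (e1 + 1 + rng.integers(0, len(_MCOD_EXTRA) - 1, size=n_total)) % len(
        _MCOD_EXTRA
    )
    e3 = (e2 + 1 + rng.integers(0, len(_MCOD_EXTRA) - 1, size=n_total)) % len(
        _MCOD_EXTRA
    )
    extras = [
        _MCOD_EXTRA[e1],
        np.where(n_extra >= 2, _MCOD_EXTRA[e2], None),
        np.where(n_extra >= 3, _MCOD_EXTRA[e3], None),
    ]

    # military-history indicator
    p_unknown = config.indicator_model["p_unknown"]
    p_yes = np.empty(n_total)
    for is_vet, grp in ((True, "p_yes_veteran"), (False, "p_yes_nonveteran")):
        for s in SEX_LEVELS:
            for b in BAND_LEVELS:
                mask = (vet == is_vet) & (sex == s) & (band == b)
                p_yes[mask] = config.indicator_model[grp][s][b]
    u = rng.random(n_total)
    military = np.where(
        u < p_yes, "yes", np.where(u < p_yes + p_unknown, "unknown", "no")
    )

    if config.ensure_unique_keys:
        death_date, dmb = _perturb_until_unique(
            rng, state, year, age, sex, ucod, dmb, filn, death_date
        )

    # emission
    report_frac = np.array(
        [config.reporting_fraction(s, int(y)) for s, y in zip(state, year)]
    )
    in_nvdrs = rng.random(n_total) < report_frac
    under = np.where(
        band == "65+",
        config.mdr_undercoverage.get("65+", config.mdr_undercoverage["default"]),
        config.mdr_undercoverage["default"],
    )
    in_mdr = vet & (rng.random(n_total) >= under)

    decedent_ids = np.arange(n_total)
    mdr = _build_mdr(config, rng, decedent_ids[in_mdr], state, year, death_date,
                     age, sex, dmb, filn, ucod, extras, manner)
    nvdrs = _build_nvdrs(config, rng, decedent_ids[in_nvdrs], state, year,
                         death_date, age, sex, dmb, filn, ucod, extras, manner,
                         military)

    both = in_mdr & in_nvdrs
    truth = pd.DataFrame(
        {
            "mdr_record_id": [f"M{i:07d}" for i in decedent_ids[both]],
            "nvdrs_record_id": [f"N{i:07d}" for i in decedent_ids[both]],
            "state": state[both],
            "year": year[both],
        }
    )
    return SimulationResult(mdr=mdr, nvdrs=nvdrs, truth=truth, config=config)


def _perturb_until_unique(rng, state, year, age, sex, ucod, dmb, filn, death_date):
    """Redraw death day and dmb for colliding decedents until the full
    six-variable key is unique within every stratum."""
    df = pd.DataFrame(
        {
            "state": state,
            "year": year,
            "age_at_death": pd.array(age, dtype="Int64"),
            "sex": sex,
            "ucod": ucod,
            "dmb": pd.array(dmb, dtype="Int64"),
            "filn": filn,
            "death_date": death_date,
        }
    )
    s1 = DEFAULT_STAGES[0]
    for _ in range(60):
        keys = stage_keys(df, s1)
        dup = keys.duplicated(keep="first")
        if not dup.any():
            break
        idx = np.flatnonzero(dup.to_numpy())
        new_doy = rng.integers(0, 365, size=len(idx))
        base = pd.to_datetime(
            pd.DataFrame(
                {"year": df.loc[dup, "year"].to_numpy(), "month": 1, "day": 1}
            )
        )
        df.loc[dup, "death_date"] = (
            base + pd.to_timedelta(new_doy, unit="D")
        ).to_numpy()
        df.loc[dup, "dmb"] = rng.integers(1, 29, size=len(idx))
    else:
        raise RuntimeError("could not de-collide stage-1 keys; stratum too dense")
    return (
        pd.to_datetime(df["death_date"]).reset_index(drop=True),
        df["dmb"].to_numpy(dtype=int),
    )


def _mcod_block(n_rows: int, ucod_col, extra_cols) -> dict:
    cols = {}
    slots = [ucod_col, *extra_cols]
    for i, col in enumerate(MCOD_COLUMNS):
        if i < len(slots):
            cols[col] = pd.array(slots[i], dtype=object)
        else:
            cols[col] = pd.array([pd.NA] * n_rows, dtype=object)
    return cols


def _build_mdr(config, rng, ids, state, year, death_date, age, sex, dmb, filn,
               ucod, extras, manner):
    k = len(ids)
    sel = ids
    df = pd.DataFrame(
        {
            "record_id": [f"M{i:07d}" for i in sel],
            "source": "MDR",
            "state": state[sel],
            "year": year[sel],
            "death_date": pd.to_datetime(np.asarray(death_date)[sel]),
            "age_at_death": pd.array(age[sel], dtype="Int64"),
            "sex": sex[sel],
            "dmb": pd.array(dmb[sel], dtype="Int64"),
            "filn": filn[sel],
            "ucod": ucod[sel],
        }
    )
    mcod_extras = [np.asarray(e, dtype=object)[sel] for e in extras]
    # a certificate occasionally drops a contributing cause
    drop_p = config.discrepancy_rates.get("mcod_drop", 0.0) / 2
    for j in range(len(mcod_extras)):
        drop = rng.random(k) < drop_p
        mcod_extras[j] = np.where(drop, None, mcod_extras[j])
    for col, vals in _mcod_block(k, df["ucod"].to_numpy(), mcod_extras).items():
        df[col] = vals
    df["manner"] = manner[sel]
    df["military_history"] = pd.NA
    df["veteran_flag"] = True

    miss = config.missingness.get("MDR", {})
    for var in ("dmb", "filn"):
        p = miss.get(var, 0.0)
        if p > 0:
            m = rng.random(k) < p
            df.loc[m, var] = pd.NA
    df = df[list(HARMONIZED_COLUMNS)]
    assert_no_dob(df)
    return df


def _build_nvdrs(config, rng, ids, state, year, death_date, age, sex, dmb, filn,
                 ucod, extras, manner, military):
    k = len(ids)
    sel = ids
    st = state[sel]
    yr = year[sel]
    dd = pd.Series(pd.to_datetime(np.asarray(death_date)[sel]))
    ag = age[sel].astype(object)
    sx = sex[sel].astype(object)
    db = dmb[sel].astype(object)
    fl = filn[sel].astype(object)
    uc = ucod[sel].copy()
    mn = manner[sel]
    mil = military[sel]
    d = config.discrepancy_rates

    # field discrepancies relative to the shared truth
    r = rng.random(k)
    small = r < d.get("death_date", 0.0)
    large = (~small) & (r < d.get("death_date", 0.0) + d.get("death_date_large", 0.0))
    shift = np.zeros(k, dtype=int)
    sign = rng.choice([-1, 1], size=k)
    shift[small] = sign[small] * rng.integers(1, 31, size=int(small.sum()))
    shift[large] = sign[large] * rng.integers(31, 365, size=int(large.sum()))
    dd = dd + pd.to_timedelta(shift, unit="D")

    rec = rng.random(k) < d.get("ucod", 0.0)
    for pool, pm in ((_SUICIDE_UCOD, "suicide"), (_UNDET_UCOD, "undetermined")):
        m = rec & (mn == pm)
        if m.any():
            uc[m] = _recode_within_pool(rng, uc[m], pool)

    typo = rng.random(k) < d.get("dmb", 0.0)
    db = np.asarray(db, dtype=object)
    db[typo] = ((db[typo].astype(int) - 1 + rng.integers(1, 28, size=int(typo.sum()))) % 28) + 1
    typo = rng.random(k) < d.get("filn", 0.0)
    fl = np.asarray(fl, dtype=object)
    idx = np.searchsorted(_FILN_LETTERS, fl[typo].astype(str))
    fl[typo] = _FILN_LETTERS[(idx + 1 + rng.integers(0, 25, size=int(typo.sum()))) % 26]

    mcod_extras = [np.asarray(e, dtype=object)[sel] for e in extras]
    drop_p = d.get("mcod_drop", 0.0)
    for j in range(len(mcod_extras)):
        drop = rng.random(k) < drop_p
        mcod_extras[j] = np.where(drop, None, mcod_extras[j])
    add = rng.random(k) < d.get("mcod_extra", 0.0)
    extra_code = np.where(
        add, _NVDRS_ONLY_MCOD[rng.integers(0, len(_NVDRS_ONLY_MCOD), size=k)], None
    )
    mcod_extras.append(extra_code)

    df = pd.DataFrame(
        {
            "record_id": [f"N{i:07d}" for i in sel],
            "source": "NVDRS",
            "state": st,
            "year": yr,
            "death_date": dd.to_numpy(),
            "age_at_death": pd.array(ag.astype(int), dtype="Int64"),
            "sex": sx,
            "dmb": pd.array(db.astype(int), dtype="Int64"),
            "filn": fl,
            "ucod": uc,
        }
    )
    # NVDRS MCOD mirrors the certificate it received, minus drops, plus extras
    for col, vals in _mcod_block(k, df["ucod"].to_numpy(), mcod_extras).items():
        df[col] = vals

    df["manner"] = mn
    df["military_history"] = mil
    df["veteran_flag"] = pd.NA

    # per-variable missingness, with per-state overrides
    var_order = ("ucod", "death_date", "dmb", "filn", "age_at_death", "sex")
    p_by_var = {
        var: np.array([config.nvdrs_missingness(s).get(var, 0.0) for s in st])
        for var in var_order
    }
    draws = {var: rng.random(k) for var in var_order}
    if config.correlated_dmb_filn:
        draws["filn"] = draws["dmb"]  # comonotone coupling: absent together
    for var in var_order:
        m = draws[var] < p_by_var[var]
        if m.any():
            if var == "death_date":
                col = df["death_date"].copy()
                col[m] = pd.NaT
                df["death_date"] = col
            else:
                df.loc[m, var] = pd.NA
    # a missing UCOD also wipes the first MCOD slot (same certificate field)
    df.loc[df["ucod"].isna(), "mcod1"] = pd.NA

    df = df[list(HARMONIZED_COLUMNS)]
    assert_no_dob(df)
    return df


def to_raw_mdr(mdr: pd.DataFrame, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Reconstruct a raw-schema MDR extract (with a full date of birth) from a
    harmonized table, for round-trip testing of the harmonizer.

    The synthesized date of birth is consistent with the record's age in
    completed years and its day-of-month of birth. Rows with missing age or
    dmb are dropped (a raw extract always carries a date of birth).
    """
    keep = mdr["age_at_death"].notna() & mdr["dmb"].notna() & mdr["death_date"].notna()
    df = mdr.loc[keep].copy()
    dobs = []
    for _, row in df.iterrows():
        dod = row["death_date"]
        age = int(row["age_at_death"])
        day = int(row["dmb"])
        if day <= dod.day:
            y, m = dod.year - age, dod.month
        else:
            y, m = (dod.year - age, dod.month - 1) if dod.month > 1 else (
                dod.year - age - 1,
                12,
            )
        dobs.append(pd.Timestamp(year=y, month=m, day=day))
    out = pd.DataFrame(
        {
            "record_id": df["record_id"],
            "state": df["state"],
            "year": df["year"],
            "date_of_birth": [t.strftime("%Y-%m-%d") for t in dobs],
            "death_date": df["death_date"].dt.strftime("%Y-%m-%d"),
            "sex": df["sex"],
            "filn": df["filn"],
            "ucod": df["ucod"],
            "veteran_flag": True,
        }
    )
    for col in MCOD_COLUMNS:
        out[col] = df[col]
    return out.reset_index(drop=True)


def write_outputs(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write mdr.csv, nvdrs.csv, truth.csv and the config echo to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mdr": out / "mdr.csv",
        "nvdrs": out / "nvdrs.csv",
        "truth": out / "truth.csv",
        "config": out / "config.yaml",
    }
    write_harmonized_csv(result.mdr, paths["mdr"])
    write_harmonized_csv(result.nvdrs, paths["nvdrs"])
    result.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    result.config.to_yaml(paths["config"])
    return paths
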