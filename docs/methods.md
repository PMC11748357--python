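# Methods

## Record model and harmonization

Both registries are reduced to one harmonized schema (`vetlink.records`).
MDR-style raw extracts carry a full date of birth; harmonization derives the
day-of-month of birth (DMB) and age at death in *completed calendar years*
(the birthday rule: age increments on the birthday itself) and then discards
the date of birth. A schema scan (`assert_no_dob`) runs on every written
table so no artifact can retain it. Records with unparseable dates or a death
date before birth are rejected with a logged reason rather than silently
dropped.

Manner of death for MDR records is classified from the underlying cause of
death (UCOD). The default code table uses the standard CDC groupings —
suicide X60–X84, Y87.0, U03; undetermined intent Y10–Y34, Y87.2, Y89.9 — and
is configurable; the table is a convention of this package, not a fact about
any particular upstream registry, and the constructor rejects overlapping
sets. NVDRS-style records keep their own manner-of-death variable. Whether
Y87.0/U03 belong in the suicide set is genuinely open; they are included by
default because excluding them only relabels a handful of sequelae/terrorism
codes and the table is a config knob.

Eligibility: manner ∈ {suicide, undetermined} and age ≥ 17 **or age
missing**. Missing-age records stay linkable (age simply voids their key in
every pass, since age is in every key) and drop out only of age-stratified
validity tables.

## Linkage

Seven passes (S1, S2a–S2d, S3a, S3b) over a concatenated key always
containing age and sex, always prefixed by the state-year stratum. Canonical
renderings: ISO dates, integer age/DMB, `M`/`F` sex, uppercased undotted
ICD-10; delimiter `|`, a character barred from all fields.

Missing-value semantics: a missing key variable voids the record's key for
that pass — missingness is never a wildcard. Variables dropped from a pass's
key are unconstrained. S3b additionally *requires* DMB and FILN to be missing
on the NVDRS side, so its effective key is {age, sex, death date} over a
deliberately information-poor pool.

Within a pass, a key held by exactly one record on each side is a match;
matched records leave both pools before the next pass. A unique-key match is
never vetoed by disagreement on non-key fields (relaxed-variable concordance
is *reported*, not enforced). Permuting input row order cannot change any
unique-key decision, and removing a pass can only reduce the total matched.

## Duplicate resolution

A key with ≥ 2 possible pairings forms a duplicate group, arbitrated by a
fixed cascade evaluated over all pairings:

1. **MCOD containment** — a pairing is supported when the MDR record's
   present MCOD codes are a subset of the NVDRS record's present codes.
   Missing NVDRS *slots* never block (certificates list up to 14 codes;
   absent slots are not evidence), but absent codes do not satisfy
   containment either; a fully missing MCOD on either side makes the pairing
   uninformative. Resolve on a unique supported pairing.
2. **Field review** — over the pass's relaxed variables: unique exact
   agreement wins; failing that, when the death date was relaxed, the unique
   strictly smallest absolute date difference wins.
3. **Military indicator** — with a single MDR candidate, a unique NVDRS
   "yes" wins. Inapplicable to multi-MDR groups (the indicator is an NVDRS
   attribute).

If every reviewed NVDRS field is missing, the group is unresolved for
insufficient information; unresolved members return to the pool. The cascade
is deterministic and candidate-order invariant. Groups with ≥ 2 records on
*both* sides resolve only through a uniquely supported pairing; ties stay
unresolved. MCOD comparison demands exact canonical-code containment
(no 3- vs 4-character "similarity"), which may under-resolve relative to a
human reviewer — a documented, conservative choice.

## Evaluation

Match rates are percentages at 2 dp, rounded half-up (exact `Decimal`
arithmetic on the integer ratio); a zero denominator is reported as
not-applicable, never 0. Stratum completeness: *not* on the partial-reporting
list (supplied via configuration, never inferred from the data) *and* at most
10% of records missing ≥ 2 linkage variables. The comparison is
strictly-greater-than (a stratum at exactly 10% is complete) and such strata
carry an `at_threshold` flag in the profile output. Concordance diagnostics
at S2a/S3b count NVDRS-UCOD missing vs present-but-different pairs, and at
S2d bucket date differences as missing / within 30 days (inclusive — the
buckets partition the pairs) / beyond 30 days.

## Indicator validity

Within complete strata, linked MDR records define status-positive records and
unlinked NVDRS records are treated as status-negative — the only
operationalization available without identifiers, and the reason MDR
under-coverage (absent Veterans) depresses measured specificity rather than
sensitivity. Unlinked MDR Veterans count as false negatives in sensitivity.
"Unknown" indicators count against accuracy in both directions but are
excluded from PPV/NPV denominators, which range over "yes" and "no" records
respectively. Each record is stratified by its own source's manner, sex and
age fields. CIs are 95% Wilson score intervals (Clopper–Pearson via config);
Wilson is the default because it behaves well at the extreme proportions the
overall strata produce.

## Synthetic generator

The generator (`vetlink.simulate`) draws a decedent universe per state-year
stratum and emits both registries plus a truth file, already in the
harmonized schema. Default study conditions (`default_study_config`):

* 8 states × 2012–2018 at 900 decedents/stratum → ~50,000 NVDRS-like and
  ~6,500 MDR-like records — the scale at which the acceptance experiments run;
* Veteran fraction 0.13; suicide (vs undetermined) 0.87; P(male) 0.95 for
  Veterans, 0.75 otherwise; age bands 17–39/40–64/65+ weighted
  0.36/0.46/0.18, uniform age within band;
* NVDRS missingness: UCOD 5.44%, death date 4.26%, DMB 12%, FILN 10%, age
  0.3%, sex 0.02%; MDR missingness ≤ 0.25% per variable (DMB/FILN only).
  One state (CO) overrides DMB/FILN missingness to 55%/50%, standing in for
  states that do not report the optional variables; an optional switch
  couples DMB/FILN missingness comonotonically;
* discrepancies on linked pairs: death date shifted 1–30 days with
  probability 0.008 plus rare 31–364-day shifts (0.002) — a two-component
  mixture so the within-30-days concordance statistic has a synthetic
  analogue; UCOD recoded within manner (0.01); DMB/FILN typos (0.005 each);
  NVDRS drops an MDR MCOD code with probability 0.05 and appends an
  NVDRS-only circumstance code with probability 0.30 (NVDRS incident records
  are typically a superset of the certificate);
* partial reporting: PA at 80% for 2016–2018; MDR under-coverage 3%,
  8% for ages 65+;
* indicator model: unconditional P(yes) for Veterans by sex × age band
  (male 0.79/0.88/0.94, female 0.50/0.63/0.75 — sex marginals ≈ 0.86 and
  0.62 under the default age mix), small positive P(yes) for non-Veterans
  (so PPV < 100%), flat P(unknown) = 0.05. Because the three probabilities
  are unconditional and sum to one with P(no), the configured Veteran
  yes-probability is exactly the quantity the sensitivity estimator targets.

FILN is drawn from a fixed surname-initial frequency table; initial
collisions inside a stratum are the natural source of duplicate groups.
`ensure_unique_keys` (used by the noise-free configuration) redraws death
day and DMB for colliding decedents until every stage-1 key is unique within
its stratum, which guarantees exact truth recovery in the noise-free limit.

What the generator does **not** model: real state-specific suicide rates or
geography beyond stratum labels, correlation between missingness and
decedent characteristics, duplicate *within-registry* records, seasonality,
or coding drift over years. Passing tests therefore demonstrate that the
pipeline's logic is correct under the stated error model, not that any
particular real-world match rate would be achieved.

## Numerical and design choices

* Missingness is injected independently per variable (only marginal rates are
  profiled in practice); the comonotone DMB/FILN switch exists for
  sensitivity analyses.
* All randomness flows from one `numpy.random.default_rng` seed; identical
  seed + config give byte-identical CSV outputs.
* Determinism in arbitration: candidates are sorted before rule evaluation;
  ties after all rules are unresolved rather than broken arbitrarily.
* Problem sizes in the test suite: oracle-equivalence strata are capped at
  200 records/side (all-pairs comparison is quadratic); the noise-free
  recovery check runs at ~10,000 records; the indicator parameter-recovery
  experiment runs 20 replicates at the full default scale.

## Known limitations

* The brute-force comparator and the keyed join agree by construction on
  equality semantics; both inherit the package's canonical renderings, so a
  systematically wrong canonicalization would not be caught by that
  comparison alone (the round-trip and classification tests cover it).
* Specificity uses the status-negative denominator (all unlinked records).
  An alternative ratio — unlinked records over indicator-"no" records — can
  exceed 1 and is not a proportion; the raw counts for both are emitted so
  either can be formed.
* With both sides of a duplicate group multiply occupied, the cascade is
  stricter than a human reviewer and may leave resolvable groups unresolved.
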