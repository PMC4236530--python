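# Methods

## The problem being modelled

Two administrative datasets are linked at the person level: hospital
admission records ("separations") spanning nine financial years
(1 July 2000 – 30 June 2009) and death registrations for the final year
(2008-09). A linkage unit's probabilistic master linkage key (MLK)
groups records belonging to the same person and serves as the reference
standard; the question is how much worse deterministic linkage through
the 14-character SLK-581 performs, alone or combined with the MLK, and
how that error propagates into estimates of hospital use before death.
Real data of this kind are confidential, so the package generates
synthetic data with the same statistical structure and carries hidden
ground truth (`true_id`) on every record, making every error exactly
measurable.

## SLK-581 construction

Names are normalised to uppercase letter sequences: Unicode-decomposed,
diacritics folded to their ASCII base letter where one exists, and all
non-alphabetic characters dropped. Positions 2, 3, 5 of the surname
and 2, 3 of the given name are extracted; position indices beyond a
short name's length yield the pad character `2`, a wholly missing name
yields `9` in every position. Date of birth renders as `DDMMYYYY`,
with `00000000` for missing *or invalid* dates; sex codes are 1 (male),
2 (female), 9 (otherwise).

Validity rules: a date of birth is invalid when missing, when the
month-day is January 1 (a data-entry sentinel), when the implied age at
the record's event date exceeds 110 years, or when it falls after the
event date. Ages over 110 are tallied under their own category; when a
date is both a January-1 sentinel and implies age over 110, the age
category takes precedence. The event date is the admission's
separation date or the registration's death date — the only per-record
date guaranteed present. Sex is invalid unless male or female. Short
names are *complete*: padding is not missingness. The three name
categories (both missing / surname only / given only) are mutually
exclusive; reasons from different component groups can co-occur on one
record.

The vectorised frame path (`add_slk_columns`) is asserted row-for-row
equivalent to the scalar path (`build_slk`) in the test suite, and
caches per unique raw name since recorded names repeat heavily.

## The synthetic study

**Population.** `n_persons` persons with canonical identities drawn
from a ~150-name pool per name type with Zipf-skewed frequencies
(exponent 1.2), so a small set of very common names dominates and
distinct persons occasionally share a key — the source of
false-positive links under exact matching. A configurable fraction
(`p_decedent`) die in the death window; age at death is Normal(81, 10)
clipped to [30, 105], matching the elderly skew of death registrations;
background persons (age 20–90) supply the collision pool. Canonical
birth dates avoid January 1 so sentinel-invalid dates arise only
through the configured process.

**Admissions.** Per-decedent counts are negative binomial with mean
12.8 over the nine years and dispersion 1.25 — the dispersion chosen so
that the zero-count probability (~5%) reproduces the ~95% of decedents
hospitalised at least once over the full window, with the long upper
tail typical of end-of-life utilisation; background persons use mean
4.0. Separation dates are uniform over the person's at-risk span
(study start to death or study end). Sector is Bernoulli with
P(public) = 0.651.

**Identity noise on records** (all independent per record): both names
blanked at 10.9% for public-sector records; for private-sector records
the missing-name rate declines linearly across financial years from
80% to 62% (mean ~71%) — the declining trend is what makes
deterministic linkage degrade with years before death, and its mean
keeps total key incompleteness near 11.3% public / 71.4% private /
32.3% overall. Dates of birth are invalidated at 0.5% (half blanked,
half set to January 1), sex at 0.01%. Independently of missingness, a
name-variant process perturbs one letter of one name on 2% of records —
a free parameter standing in for spelling variation, nicknames and name
changes, which is what makes exact-key linkage diverge from truth even
when names are present.

**Deaths.** One registration per decedent plus duplicates at 0.3%
(mirroring the ~0.3% duplicate rate implied by registry counts).
Incomplete at 0.6%, composed 97% invalid date of birth, 1.5% missing
surname, 1.5% invalid sex; both names are never blank on death records,
matching the observed composition of registry data.

**Conditions** are abstract labels attached per admission with a
per-admission base rate and a private-sector affinity (0.5 neutral):
arthritis-like labels concentrate in private records, diabetes-like in
public ones. This is the minimal mechanism needed to show
condition-dependent linkage bias; it makes no attempt at clinical
coding realism.

**Master linkage key.** The truth grouping sets `person_key = true_id`.
`perturb_mlk` injects, per record, a split into a fresh singleton key
(missed link, probability 5/1000) or a reassignment to another record's
group (false-positive link, 3/1000). The pipeline weights the
injection onto records whose SLK-581 is incomplete, preserving the
overall per-record rates: probabilistic linkage fails predominantly
where identifiers are poor, and uniform injection would let the SLK
"rescue" MLK-dropped well-identified records, inflating measured
false-positive person rates two orders of magnitude above the error
scale this design reproduces. The bare function defaults to uniform
injection.

**Error measurement** (`measure_mlk_errors`) uses a per-record,
mutually exclusive taxonomy: each perturbed group is attributed to the
person holding the plurality of its records; a record not of its
group's plurality person is a *false positive* (an intruder); a record
sharing its group with none of its true peers, while peers exist, and
not an intruder, is *missed* (a pure split-out). Realized rates
therefore estimate the injection rates directly; pairwise definitions
would count each reassignment as both missed and false.

**Determinism.** One master seed; every generation stage (persons,
admissions, deaths, MLK perturbation, duplicate-death selection) draws
from its own `SeedSequence([seed, stage])` substream, so changing one
stage's parameters does not shift another stage's draws. All outputs
are byte-identical across runs at a fixed seed.

## Linkage strategies

Matching is exact equality of the full 14-character string, dummy
characters included — an all-dummy name block matches only another
record missing the same components, which is what keeps false-positive
rates low under heavy missingness. Incomplete keys participate like
any other value. Duplicate death registrations are resolved once
(uniform random, seeded) and the same retained set feeds all five
strategies. A death whose key matches more than one MLK person links
to the union of their records and is flagged ambiguous — the
sensitivity-maximising reading, with the flag preserving auditability.
"Most recent" orders by separation date with exact-date ties broken by
largest record id, for reproducibility. The most-frequent rule counts
complete keys only (falling back to incomplete keys when a person has
no complete one), breaking frequency ties by the most recent bearer.
The reference strategy is not a probabilistic engine: it consumes the
supplied MLK grouping as given, exactly as a study receives linkage
keys from a linkage unit.

## Evaluation

* Denominator for utilisation statistics (percentage hospitalised,
  mean, median, quartiles): **all** retained death records, unlinked
  included and counted as zero — the convention under which linked
  persons ÷ retained deaths and linked records ÷ retained deaths
  reproduce published-style summary tables exactly.
* Denominator for person-level missed / false-positive rates: retained
  deaths with at least one reference-linked record (a person the
  reference never linked can have no missed link); the same denominator
  is used for both rates so they are comparable.
* Window membership uses the financial year (July–June) of the
  separation date; look-back windows are spans of financial years
  ending at the death year. The condition table uses the full
  nine-year window.
* The per-year error trend is indexed by the financial year of the
  *admission* records (all deaths fall in one year, so a trend by year
  of death would be degenerate): for year y, the denominator is
  decedents with a reference record in y, and a decedent is
  missed/false in y when the corresponding set difference contains a
  record dated y.
* 95% CI for the mean: normal approximation, mean ± 1.96·sd/√n — the
  simplest defensible default, isolated in one place and swappable.
* Rounding for report output: percentages and means to 1 d.p., rate
  ratios to 2 d.p.

## Problem sizes

The shipped analysis uses 6 000 persons (≈55 000 admission records);
calibration checks and the acceptance script use 10 000 persons
(≈100 000 admissions, ≈105 000 records under the MLK). Statistical
assertions use three-binomial-standard-error tolerances at the relevant
n. These sizes give stable rates while keeping any single run under a
minute.

## What passing tests do and do not show

The generator reproduces the *marginal* structure of the motivating
setting: sector mix, sector- and time-specific name missingness,
component composition of incomplete keys, duplicate and incomplete
death registrations, over-dispersed utilisation, and bounded MLK error.
It does not model person-level sector loyalty (sector is drawn per
record), clinically coherent condition histories, household or
geographic structure, true name-change processes (variants are
per-record and memoryless), or migration in and out of the population.
Consequently person-level error rates are comparable in structure but
not in level to any real collection — the package demonstrates
*mechanisms* (which strategy misses what, and why), and its
quantitative claims are about its own calibrated study conditions.

Known limitations: the name pools are Anglo-centric by design (matching
the historical composition of the emulated registries) and the
per-record independence of noise makes person-level miss rates higher
than sector-correlated noise would produce; the ambiguous-match union
rule slightly favours sensitivity over precision and is flagged rather
than resolved.
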