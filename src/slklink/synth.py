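"""Synthetic hospital-admission and death-registration data with ground truth.

Emulates the statistical structure of a state-wide administrative
linkage study: a population of persons, each with canonical identifiers;
per-person hospital separations over a nine-financial-year window with a
public/private sector mix; death registrations (with occasional
duplicates) for the decedent subset over the final year; and a
"master linkage key" (MLK) — the person-level grouping a linkage unit
would supply from probabilistic linkage — derivable either as exact
ground truth or with missed-link / false-positive-link errors injected
at configurable per-record rates.

Calibration targets, all configurable:

* sector mix 65.1% public / 34.9% private;
* both names missing on 10.9% of public-sector records and on a
  declining share of private-sector records (80% at the start of the
  study to 62% at its end, averaging ~71%), so that total key
  incompleteness lands near 11.3% public / 71.4% private / 32.3%
  overall;
* missing/invalid dates of birth on 0.5% of records and invalid sex on
  ~0.01%;
* deaths incomplete at 0.6%, almost always via the date of birth, with
  names always present;
* ~12.8 hospital separations per decedent over nine years, drawn from a
  negative binomial so the count distribution has the long upper tail
  typical of end-of-life utilisation;
* MLK error injection at 5/1000 missed and 3/1000 false-positive links.

Identity noise that drives deterministic-linkage error: sector- and
time-dependent name missingness, occasional name variants (spelling
perturbations), invalid dates of birth (blanked or set to the January-1
sentinel) and invalid sex.  Hidden truth (``true_id``) is carried on
every record so linkage error is measurable exactly.

Determinism: one master seed; each generation stage draws from its own
substream, so changing one stage's parameters does not shift another
stage's draws.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd

from ._names import SURNAMES, GIVEN_NAMES
from .errors import ConfigError
from .slk581 import PersonIdentity

__all__ = [
    "SynthConfig",
    "generate_population",
    "generate_admissions",
    "generate_deaths",
    "apply_missingness",
    "build_true_mlk",
    "perturb_mlk",
    "measure_mlk_errors",
    "simulate",
]

# substream ids (stable across releases; see D17-style seeding note in docs)
_STREAM_PERSONS = 0
_STREAM_ADMISSIONS = 1
_STREAM_DEATHS = 2
_STREAM_MLK = 3
STREAM_DEDUPE = 4

_JAN1_SENTINEL_SHARE = 0.5  # invalid DOBs: half blanked, half January-1


def _default_conditions() -> dict:
    """Abstract condition labels: per-admission base rate and private-
    sector affinity (0.5 neutral, >0.5 concentrates in private records).

    Labels mirror common health priority areas; the arthritis-style
    private affinity and diabetes-style public affinity let evaluation
    demonstrate condition-dependent linkage bias.
    """
    return {
        "cancer": (0.060, 0.50),
        "cardiovascular": (0.090, 0.45),
        "mental_illness": (0.020, 0.40),
        "asthma": (0.003, 0.50),
        "arthritis": (0.030, 0.85),
        "diabetes": (0.035, 0.25),
        "injury": (0.080, 0.50),
        "acsc": (0.090, 0.40),
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.  Defaults are the study-scale
    calibration described in the module docstring."""

    n_persons: int = 5000
    p_decedent: float = 0.5
    study_start: date = date(2000, 7, 1)
    study_end: date = date(2009, 6, 30)
    death_window_start: date = date(2008, 7, 1)
    death_window_end: date = date(2009, 6, 30)
    p_public: float = 0.651
    missing_name_rate_public: float = 0.109
    #: flat private-sector missing-name rate; ``None`` -> linear trend
    missing_name_rate_private: float | None = None
    missing_name_rate_private_start: float = 0.80
    missing_name_rate_private_end: float = 0.62
    invalid_dob_rate: float = 0.005
    invalid_sex_rate: float = 0.0001
    death_incomplete_rate: float = 0.006
    duplicate_death_rate: float = 0.003
    admissions_mean: float = 12.8
    admissions_dispersion: float = 1.25
    background_admissions_mean: float = 4.0
    mlk_missed_rate: float = 0.005
    mlk_fp_rate: float = 0.003
    name_variant_rate: float = 0.02
    name_pool_size: int = 150
    name_zipf_exponent: float = 1.2
    condition_prevalences: dict = field(default_factory=_default_conditions)
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be non-negative")
        props = {
            "p_decedent": self.p_decedent,
            "p_public": self.p_public,
            "missing_name_rate_public": self.missing_name_rate_public,
            "missing_name_rate_private_start": self.missing_name_rate_private_start,
            "missing_name_rate_private_end": self.missing_name_rate_private_end,
            "invalid_dob_rate": self.invalid_dob_rate,
            "invalid_sex_rate": self.invalid_sex_rate,
            "death_incomplete_rate": self.death_incomplete_rate,
            "duplicate_death_rate": self.duplicate_death_rate,
            "mlk_missed_rate": self.mlk_missed_rate,
            "mlk_fp_rate": self.mlk_fp_rate,
            "name_variant_rate": self.name_variant_rate,
        }
        if self.missing_name_rate_private is not None:
            props["missing_name_rate_private"] = self.missing_name_rate_private
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mlk_missed_rate + self.mlk_fp_rate > 1.0:
            raise ConfigError("mlk_missed_rate + mlk_fp_rate must not exceed 1")
        if not self.study_start < self.study_end:
            raise ConfigError("study_start must precede study_end")
        if not self.death_window_start < self.death_window_end:
            raise ConfigError("death window dates out of order")
        if self.admissions_mean < 0 or self.background_admissions_mean < 0:
            raise ConfigError("admission means must be non-negative")
        if self.admissions_dispersion <= 0:
            raise ConfigError("admissions_dispersion must be positive")
        if not 1 <= self.name_pool_size <= min(len(SURNAMES), len(GIVEN_NAMES)):
            raise ConfigError(
                f"name_pool_size must be in [1, {min(len(SURNAMES), len(GIVEN_NAMES))}]"
            )
        for label, (prev, aff) in self.condition_prevalences.items():
            if not (0 <= prev <= 0.5 and 0 <= aff <= 1):
                raise ConfigError(f"condition {label!r} has invalid parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, date):
                d[k] = v.isoformat()
        return d

    def private_missing_rate(self, fin_year: int) -> float:
        """Private-sector missing-name rate for one financial year
        (identified by its July starting year)."""
        if self.missing_name_rate_private is not None:
            return self.missing_name_rate_private
        start_fy = _fy(self.study_start)
        end_fy = _fy(self.study_end - pd.Timedelta(days=1))
        span = max(end_fy - start_fy, 1)
        t = np.clip((fin_year - start_fy) / span, 0.0, 1.0)
        lo, hi = self.missing_name_rate_private_start, self.missing_name_rate_private_end
        return float(lo + (hi - lo) * t)


def _fy(d) -> int:
    """Financial year (July-June) starting-year of a date."""
    return d.year if d.month >= 7 else d.year - 1


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _zipf_pool(names: list, size: int, exponent: float):
    pool = np.array([n for n in names[:size]])
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks**-exponent
    return pool, w / w.sum()


_PERSON_COLUMNS = ["true_id", "surname", "given_name", "birth_date", "sex", "death_date"]
_ADMISSION_COLUMNS = [
    "record_id", "true_id", "surname", "given_name", "birth_date", "sex",
    "separation_date", "sector", "conditions",
]
_DEATH_COLUMNS = [
    "record_id", "true_id", "surname", "given_name", "birth_date", "sex", "death_date",
]


def generate_population(config: SynthConfig) -> pd.DataFrame:
    """Generate the person table with canonical identities and hidden truth.

    A configurable fraction are decedents (death date uniform in the
    death window, age at death ~ Normal(81, 10) clipped to [30, 105]);
    the rest are background persons (age 20-90 at study end) whose
    admissions provide the collision pool for false-positive links.
    Canonical birth dates avoid January 1 so sentinel-invalid dates
    arise only through the configured invalidation process.
    """
    config.validate()
    n = config.n_persons
    if n == 0:
        return pd.DataFrame(columns=_PERSON_COLUMNS)
    rng = _rng(config, _STREAM_PERSONS)
    sur_pool, sur_p = _zipf_pool(SURNAMES, config.name_pool_size, config.name_zipf_exponent)
    giv_pool, giv_p = _zipf_pool(GIVEN_NAMES, config.name_pool_size, config.name_zipf_exponent)

    surname = rng.choice(sur_pool, size=n, p=sur_p)
    given = rng.choice(giv_pool, size=n, p=giv_p)
    sex = rng.choice(np.array(["male", "female"]), size=n)
    is_dec = rng.random(n) < config.p_decedent

    dw_start = pd.Timestamp(config.death_window_start)
    dw_days = (pd.Timestamp(config.death_window_end) - dw_start).days
    death_offset = rng.integers(0, dw_days + 1, size=n)
    death_date = dw_start + pd.to_timedelta(death_offset, unit="D")

    age_dec = np.clip(rng.normal(81.0, 10.0, size=n), 30.0, 105.0)
    age_bg = rng.uniform(20.0, 90.0, size=n)
    ref = pd.Series(death_date).where(pd.Series(is_dec), pd.Timestamp(config.study_end))
    age = np.where(is_dec, age_dec, age_bg) + rng.random(n)  # fractional years
    birth = ref - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")
    # avoid the January-1 sentinel in canonical identities
    jan1 = (birth.dt.month == 1) & (birth.dt.day == 1)
    birth = birth + pd.to_timedelta(jan1.astype(int), unit="D")

    return pd.DataFrame(
        {
            "true_id": [f"P{i:06d}" for i in range(n)],
            "surname": surname,
            "given_name": given,
            "birth_date": birth,
            "sex": sex,
            "death_date": pd.Series(death_date).where(pd.Series(is_dec), pd.NaT),
        }
    )


def apply_missingness(
    identity: PersonIdentity,
    sector: str,
    config: SynthConfig,
    rng: np.random.Generator,
    event_date: date | None = None,
) -> PersonIdentity:
    """Degrade one recorded identity with the sector's missingness model.

    Both names are blanked at the sector (and, for private records,
    financial-year) missing-name rate; the date of birth is invalidated
    (blanked or set to January 1) at ``invalid_dob_rate``; sex is
    invalidated at ``invalid_sex_rate``.  The three events are
    independent.
    """
    if sector == "public":
        name_rate = config.missing_name_rate_public
    else:
        fy = _fy(event_date) if event_date is not None else _fy(config.study_start)
        if event_date is None and config.missing_name_rate_private is None:
            # no event date: use the trend's midpoint
            name_rate = (config.missing_name_rate_private_start
                         + config.missing_name_rate_private_end) / 2.0
        else:
            name_rate = config.private_missing_rate(fy)
    surname, given_name = identity.surname, identity.given_name
    birth_date, sex = identity.birth_date, identity.sex
    if rng.random() < name_rate:
        surname = None
        given_name = None
    if rng.random() < config.invalid_dob_rate:
        if rng.random() < _JAN1_SENTINEL_SHARE and birth_date is not None:
            birth_date = date(birth_date.year, 1, 1)
        else:
            birth_date = None
    if rng.random() < config.invalid_sex_rate:
        sex = None
    return PersonIdentity(surname, given_name, birth_date, sex)


def _perturb_names(surname, given, variant_mask, rng):
    """Spelling-perturb one letter of surname or given name on flagged
    rows; this is what makes exact-key linkage diverge from truth even
    when names are present."""
    letters = np.array(list(string.ascii_uppercase))
    surname = surname.astype(object).copy()
    given = given.astype(object).copy()
    for i in np.flatnonzero(variant_mask):
        target_surname = rng.random() < 0.5
        name = surname[i] if target_surname else given[i]
        if not name:
            continue
        pos = int(rng.integers(0, len(name)))
        repl = str(rng.choice(letters))
        new = name[:pos] + repl + name[pos + 1:]
        if target_surname:
            surname[i] = new
        else:
            given[i] = new
    return surname, given


def generate_admissions(persons: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Generate hospital-separation records for a person table.

    Per-person record counts are negative binomial (decedents at
    ``admissions_mean``, background persons at
    ``background_admissions_mean``, shared dispersion); separation dates
    are uniform over the person's at-risk span (study start to death or
    study end); sector is Bernoulli(``p_public``); recorded identities
    are the canonical identities degraded by the name-variant and
    missingness processes; condition labels attach per record with
    sector-affine probabilities.
    """
    config.validate()
    if persons.empty:
        return pd.DataFrame(columns=_ADMISSION_COLUMNS)
    rng = _rng(config, _STREAM_ADMISSIONS)

    is_dec = persons["death_date"].notna().to_numpy()
    mean = np.where(is_dec, config.admissions_mean, config.background_admissions_mean)
    r = config.admissions_dispersion
    counts = np.where(
        mean > 0, rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12))), 0
    ).astype(int)

    m = int(counts.sum())
    if m == 0:
        return pd.DataFrame(columns=_ADMISSION_COLUMNS)
    idx = np.repeat(np.arange(len(persons)), counts)

    start = pd.Timestamp(config.study_start)
    end_person = (
        persons["death_date"].fillna(pd.Timestamp(config.study_end)).to_numpy()
    )
    span_days = ((end_person - np.datetime64(start)) / np.timedelta64(1, "D")).astype(int)
    sep_offset = rng.integers(0, span_days[idx] + 1)
    sep = start + pd.to_timedelta(sep_offset, unit="D")

    sector = np.where(rng.random(m) < config.p_public, "public", "private")

    # conditions, sector-affine
    labels = [np.array([], dtype=object)] * m
    cond_parts = []
    for label, (base, affinity) in config.condition_prevalences.items():
        p = np.where(sector == "private", 2.0 * base * affinity,
                     2.0 * base * (1.0 - affinity))
        cond_parts.append((label, rng.random(m) < np.clip(p, 0.0, 1.0)))
    conditions = [
        ";".join(lab for lab, mask in cond_parts if mask[i]) for i in range(m)
    ]

    surname = persons["surname"].to_numpy()[idx]
    given = persons["given_name"].to_numpy()[idx]
    birth = pd.Series(persons["birth_date"].to_numpy()[idx])
    sex = persons["sex"].to_numpy()[idx].astype(object)

    variant = rng.random(m) < config.name_variant_rate
    surname, given = _perturb_names(surname, given, variant, rng)

    fy = pd.Series(sep).map(_fy).to_numpy()
    rate_private = np.array([config.private_missing_rate(y) for y in fy])
    name_rate = np.where(sector == "public", config.missing_name_rate_public, rate_private)
    miss_names = rng.random(m) < name_rate
    surname[miss_names] = None
    given[miss_names] = None

    bad_dob = rng.random(m) < config.invalid_dob_rate
    jan1 = bad_dob & (rng.random(m) < _JAN1_SENTINEL_SHARE)
    blank = bad_dob & ~jan1
    birth = birth.where(~blank, pd.NaT)
    if jan1.any():
        years = birth.dt.year.where(birth.notna(), 1900).astype(int)
        birth = birth.where(
            ~jan1, pd.to_datetime({"year": years, "month": 1, "day": 1})
        )
    bad_sex = rng.random(m) < config.invalid_sex_rate
    sex[bad_sex] = None

    return pd.DataFrame(
        {
            "record_id": [f"A{i:07d}" for i in range(m)],
            "true_id": persons["true_id"].to_numpy()[idx],
            "surname": surname,
            "given_name": given,
            "birth_date": birth.to_numpy(),
            "sex": sex,
            "separation_date": sep,
            "sector": sector,
            "conditions": conditions,
        }
    )


def generate_deaths(persons: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Generate death-registration records for the decedent subset.

    One record per decedent, plus duplicate registrations at
    ``duplicate_death_rate``.  Recorded identities are incomplete at
    ``death_incomplete_rate``, predominantly via an invalidated date of
    birth (names are never blanked on death records, mirroring
    registry practice); small shares go to a missing surname or
    invalid sex.
    """
    config.validate()
    dec = persons[persons["death_date"].notna()].reset_index(drop=True)
    if dec.empty:
        return pd.DataFrame(columns=_DEATH_COLUMNS)
    rng = _rng(config, _STREAM_DEATHS)
    n = len(dec)

    surname = dec["surname"].to_numpy().astype(object)
    given = dec["given_name"].to_numpy().astype(object)
    birth = pd.Series(dec["birth_date"].to_numpy())
    sex = dec["sex"].to_numpy().astype(object)

    incomplete = rng.random(n) < config.death_incomplete_rate
    # composition of incomplete death keys: DOB 97%, surname 1.5%, sex 1.5%
    mech = rng.choice(np.array(["dob", "surname", "sex"]), size=n,
                      p=[0.97, 0.015, 0.015])
    bad_dob = incomplete & (mech == "dob")
    jan1 = bad_dob & (rng.random(n) < _JAN1_SENTINEL_SHARE)
    blank = bad_dob & ~jan1
    birth = birth.where(~blank, pd.NaT)
    if jan1.any():
        years = birth.dt.year.where(birth.notna(), 1900).astype(int)
        birth = birth.where(
            ~jan1, pd.to_datetime({"year": years, "month": 1, "day": 1})
        )
    surname[incomplete & (mech == "surname")] = None
    sex[incomplete & (mech == "sex")] = None

    out = pd.DataFrame(
        {
            "record_id": [f"D{i:06d}" for i in range(n)],
            "true_id": dec["true_id"].to_numpy(),
            "surname": surname,
            "given_name": given,
            "birth_date": birth.to_numpy(),
            "sex": sex,
            "death_date": dec["death_date"].to_numpy(),
        }
    )
    dup = rng.random(n) < config.duplicate_death_rate
    if dup.any():
        dups = out.loc[dup].copy()
        dups["record_id"] = [f"D{i:06d}" for i in range(n, n + len(dups))]
        out = pd.concat([out, dups], ignore_index=True)
    return out


def build_true_mlk(admissions: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """The ground-truth person grouping: person_key == true_id."""
    parts = []
    for df in (admissions, deaths):
        if not df.empty:
            parts.append(df[["record_id", "true_id"]].rename(columns={"true_id": "person_key"}))
    if not parts:
        return pd.DataFrame(columns=["record_id", "person_key"])
    out = pd.concat(parts, ignore_index=True)
    if out["record_id"].duplicated().any():
        dupe = out.loc[out["record_id"].duplicated(), "record_id"].iloc[0]
        raise ConfigError(f"duplicate record id {dupe!r} across datasets")
    return out


def perturb_mlk(
    true_mlk: pd.DataFrame,
    missed_rate: float,
    fp_rate: float,
    seed: int,
    weights=None,
) -> pd.DataFrame:
    """Inject linkage errors into a person grouping.

    Per record, with probability ``missed_rate`` the record is split out
    of its group into a fresh singleton key (a missed link); otherwise,
    with probability ``fp_rate``, it is reassigned to the (original)
    group of a uniformly drawn other record (a false-positive link).
    Deterministic given ``seed``.

    ``weights`` (optional, aligned to rows) skews *where* errors land
    while preserving the overall per-record rates: per-record
    probabilities are the nominal rates scaled by ``w * n / sum(w)``.
    Probabilistic linkage fails mostly where identifiers are poor, so
    the pipeline weights errors onto records with incomplete keys; a
    zero/None weight vector falls back to uniform.
    """
    if not (0 <= missed_rate <= 1 and 0 <= fp_rate <= 1 and missed_rate + fp_rate <= 1):
        raise ConfigError("perturbation rates must be proportions summing to <= 1")
    out = true_mlk.reset_index(drop=True).copy()
    n = len(out)
    if n == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_MLK]))
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any():
            raise ConfigError("weights must be non-negative and aligned to the MLK")
        if w.sum() == 0:
            w = np.ones(n)
    scale = w * (n / w.sum())
    p_missed = np.minimum(missed_rate * scale, 1.0)
    p_fp = np.minimum(fp_rate * scale, 1.0 - p_missed)
    u = rng.random(n)
    missed = u < p_missed
    fp = (~missed) & (u < p_missed + p_fp)
    keys = out["person_key"].to_numpy().astype(object)
    original = keys.copy()
    keys[missed] = np.array(
        ["S" + rid for rid in out.loc[missed, "record_id"]], dtype=object
    ) if missed.any() else keys[missed]
    if fp.any():
        donors = rng.integers(0, n, size=int(fp.sum()))
        keys[np.flatnonzero(fp)] = original[donors]
    out["person_key"] = keys
    return out


def measure_mlk_errors(true_mlk: pd.DataFrame, perturbed_mlk: pd.DataFrame) -> dict:
    """Measure realized per-record linkage-error rates against truth.

    Each perturbed group is attributed to the person holding the
    plurality of its records.  A record is a *false positive* when it is
    not of its group's plurality person (an intruder among someone
    else's records).  It is *missed* when it shares its group with none
    of its true peers although peers exist, and it is not an intruder (a
    pure split-out).  The categories are mutually exclusive, so at small
    rates the realized values estimate the injection rates directly.

    Returns ``{"missed_rate", "fp_rate", "n"}`` with rates per record.
    """
    df = true_mlk.rename(columns={"person_key": "true_key"}).merge(
        perturbed_mlk, on="record_id", validate="one_to_one"
    )
    n = len(df)
    if n == 0:
        return {"missed_rate": 0.0, "fp_rate": 0.0, "n": 0}
    cell = (
        df.groupby(["person_key", "true_key"], sort=False).size().reset_index(name="n_cell")
    )
    plurality = (
        cell.sort_values(["person_key", "n_cell", "true_key"])
        .groupby("person_key", sort=False)
        .tail(1)
        .set_index("person_key")["true_key"]
    )
    df["fp"] = df["true_key"].to_numpy() != df["person_key"].map(plurality).to_numpy()
    df = df.merge(cell, on=["person_key", "true_key"], how="left")
    person_total = df.groupby("true_key")["record_id"].transform("size")
    alone = df["n_cell"] == 1
    has_peers = person_total > 1
    df["missed"] = ~df["fp"] & alone & has_peers
    return {
        "missed_rate": float(df["missed"].mean()),
        "fp_rate": float(df["fp"].mean()),
        "n": n,
    }


def simulate(config: SynthConfig) -> dict:
    """Run the full generation pipeline.

    Returns a dict with ``persons``, ``admissions``, ``deaths``,
    ``mlk_true`` and ``mlk`` (the error-injected grouping at the
    configured rates, the probabilistic-linkage stand-in that the
    linkage strategies consume).  MLK errors are weighted onto records
    whose SLK-581 is incomplete — probabilistic linkage fails mostly
    where identifiers are poor — while the overall per-record error
    rates stay at the configured values.
    """
    from .slk581 import add_slk_columns

    persons = generate_population(config)
    admissions = generate_admissions(persons, config)
    deaths = generate_deaths(persons, config)
    mlk_true = build_true_mlk(admissions, deaths)
    incomplete_ids: set = set()
    if not admissions.empty:
        adm_slk = add_slk_columns(admissions, event_col="separation_date")
        incomplete_ids |= set(adm_slk.loc[~adm_slk["slk_complete"], "record_id"])
    if not deaths.empty:
        dth_slk = add_slk_columns(deaths, event_col="death_date")
        incomplete_ids |= set(dth_slk.loc[~dth_slk["slk_complete"], "record_id"])
    weights = mlk_true["record_id"].isin(incomplete_ids).to_numpy(dtype=float)
    mlk = perturb_mlk(
        mlk_true, config.mlk_missed_rate, config.mlk_fp_rate, config.seed,
        weights=weights,
    )
    return {
        "persons": persons,
        "admissions": admissions,
        "deaths": deaths,
        "mlk_true": mlk_true,
        "mlk": mlk,
    }
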