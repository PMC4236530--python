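from datetime import date

import pandas as pd
import pytest

from slklink import linkage, synth


def make_admissions(rows):
    """Build an admissions frame from partial row dicts."""
    defaults = {
        "true_id": "P1",
        "surname": "Taylor",
        "given_name": "Lee",
        "birth_date": pd.Timestamp(1946, 9, 5),
        "sex": "male",
        "separation_date": pd.Timestamp(2008, 1, 1),
        "sector": "public",
        "conditions": "",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_deaths(rows):
    defaults = {
        "true_id": "P1",
        "surname": "Taylor",
        "given_name": "Lee",
        "birth_date": pd.Timestamp(1946, 9, 5),
        "sex": "male",
        "death_date": pd.Timestamp(2008, 9, 1),
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_mlk(pairs):
    return pd.DataFrame(pairs, columns=["record_id", "person_key"])


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized default-configuration study, shared across
    tests that only read from it."""
    cfg = synth.SynthConfig(n_persons=3000, seed=7)
    data = synth.simulate(cfg)
    retained = linkage.dedupe_deaths(data["deaths"], data["mlk"], cfg.seed)
    results = linkage.run_all_strategies(retained, data["admissions"], data["mlk"])
    return {"config": cfg, **data, "retained": retained, "results": results}


@pytest.fixture(scope="session")
def noise_free_sim():
    """A study with every noise channel switched off and persons
    filtered to unique SLKs: the regime where all five strategies must
    coincide."""
    cfg = synth.SynthConfig(
        n_persons=800,
        seed=11,
        missing_name_rate_public=0.0,
        missing_name_rate_private=0.0,
        invalid_dob_rate=0.0,
        invalid_sex_rate=0.0,
        death_incomplete_rate=0.0,
        duplicate_death_rate=0.0,
        name_variant_rate=0.0,
        mlk_missed_rate=0.0,
        mlk_fp_rate=0.0,
    )
    persons = synth.generate_population(cfg)
    from slklink.slk581 import add_slk_columns

    pk = add_slk_columns(
        persons.assign(event_date=pd.Timestamp(cfg.study_end)), event_col="event_date"
    )
    unique = pk[~pk.duplicated(subset="slk", keep=False)]
    persons = persons.loc[unique.index].reset_index(drop=True)
    admissions = synth.generate_admissions(persons, cfg)
    deaths = synth.generate_deaths(persons, cfg)
    mlk = synth.build_true_mlk(admissions, deaths)
    retained = linkage.dedupe_deaths(deaths, mlk, cfg.seed)
    results = linkage.run_all_strategies(retained, admissions, mlk)
    return {
        "config": cfg,
        "persons": persons,
        "admissions": admissions,
        "deaths": deaths,
        "mlk": mlk,
        "retained": retained,
        "results": results,
    }
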