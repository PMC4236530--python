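"""Tests of the five linkage strategies on hand-built micro-datasets and
generated studies."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_admissions, make_deaths, make_mlk
from slklink import linkage
from slklink.errors import DataError
from slklink.linkage import (
    ANY_MATCH,
    BASIC,
    FULL_PROBABILISTIC,
    MOST_FREQUENT,
    MOST_RECENT,
    STRATEGIES,
    dedupe_deaths,
    link_any_match,
    link_basic_slk,
    link_full_probabilistic,
    link_via_person_slk,
    person_slk_most_frequent,
    person_slk_most_recent,
    run_strategy,
    with_slk,
)

T = pd.Timestamp


# -- duplicate-death resolution ---------------------------------------------


def test_dedupe_without_duplicates_is_identity():
    deaths = make_deaths([{"record_id": "D1"}, {"record_id": "D2", "true_id": "P2"}])
    mlk = make_mlk([("D1", "P1"), ("D2", "P2")])
    out = dedupe_deaths(deaths, mlk, seed=1)
    assert sorted(out["record_id"]) == ["D1", "D2"]


def test_dedupe_retains_one_record_per_person_and_is_deterministic():
    deaths = make_deaths(
        [{"record_id": "D1"}, {"record_id": "D2"}, {"record_id": "D3", "true_id": "P2"}]
    )
    mlk = make_mlk([("D1", "P1"), ("D2", "P1"), ("D3", "P2")])
    out1 = dedupe_deaths(deaths, mlk, seed=42)
    out2 = dedupe_deaths(deaths, mlk, seed=42)
    assert len(out1) == 2
    assert set(out1["record_id"]) & {"D1", "D2"}
    pd.testing.assert_frame_equal(out1, out2)


# -- strategy 1: follow the MLK ---------------------------------------------


def test_full_probabilistic_follows_grouping():
    deaths = make_deaths([{"record_id": "D1"}, {"record_id": "D2", "true_id": "P2"}])
    adm = make_admissions(
        [{"record_id": "A1"}, {"record_id": "A2"}, {"record_id": "A3", "true_id": "P3"}]
    )
    mlk = make_mlk(
        [("D1", "P1"), ("D2", "P2"), ("A1", "P1"), ("A2", "P1"), ("A3", "P3")]
    )
    res = link_full_probabilistic(deaths, adm, mlk)
    assert res.links["D1"] == frozenset({"A1", "A2"})
    assert res.links["D2"] == frozenset()  # person with no admissions


def test_full_probabilistic_respects_a_perturbed_grouping():
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions([{"record_id": "A1"}, {"record_id": "A2"}])
    mlk = make_mlk([("D1", "P1"), ("A1", "S_A1"), ("A2", "P1")])  # A1 split out
    res = link_full_probabilistic(deaths, adm, mlk)
    assert res.links["D1"] == frozenset({"A2"})


def test_missing_record_id_in_mlk_raises_with_the_id():
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions([{"record_id": "A1"}])
    mlk = make_mlk([("D1", "P1")])
    with pytest.raises(DataError, match="A1"):
        link_full_probabilistic(deaths, adm, mlk)


# -- strategy 2: basic SLK ---------------------------------------------------


def test_basic_slk_exact_match_only():
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions(
        [
            {"record_id": "A1"},  # same identity -> same key
            {"record_id": "A2", "surname": None, "given_name": None},  # dummy key
            {"record_id": "A3", "surname": "Brown", "given_name": "Ann"},
        ]
    )
    res = link_basic_slk(deaths, adm)
    assert res.links["D1"] == frozenset({"A1"})


def test_basic_slk_no_match_gives_empty_set():
    deaths = make_deaths([{"record_id": "D1", "surname": "Zed", "given_name": "Quinn"}])
    adm = make_admissions([{"record_id": "A1"}])
    assert link_basic_slk(deaths, adm).links["D1"] == frozenset()


def test_incomplete_keys_match_only_identically_dummy_filled_keys():
    deaths = make_deaths([{"record_id": "D1", "surname": None, "given_name": None}])
    adm = make_admissions(
        [
            {"record_id": "A1", "surname": None, "given_name": None},
            {"record_id": "A2"},
        ]
    )
    assert link_basic_slk(deaths, adm).links["D1"] == frozenset({"A1"})


# -- strategies 3/4: representative person keys ------------------------------


def _person_records(spec):
    """spec: list of (record_id, year, surname or None) all for person P1."""
    rows = []
    for rid, year, surname in spec:
        rows.append(
            {
                "record_id": rid,
                "separation_date": T(year, 6, 1),
                **({"surname": surname, "given_name": None if surname is None else "Lee"}
                   if surname is None else {"surname": surname}),
            }
        )
    adm = make_admissions(rows)
    mlk = make_mlk([(rid, "P1") for rid, _, _ in spec])
    return adm, mlk


def test_most_recent_prefers_latest_complete_key():
    adm, mlk = _person_records([("A1", 2005, "Taylor"), ("A2", 2008, "Brown")])
    rep = person_slk_most_recent(adm, mlk)
    assert rep["P1"] == with_slk(adm, "separation_date").set_index("record_id")["slk"]["A2"]


def test_most_recent_prefers_complete_over_recency():
    adm, mlk = _person_records([("A1", 2005, "Taylor"), ("A2", 2008, None)])
    rep = person_slk_most_recent(adm, mlk)
    keyed = with_slk(adm, "separation_date").set_index("record_id")["slk"]
    assert rep["P1"] == keyed["A1"]


def test_most_recent_falls_back_to_latest_incomplete_key():
    adm, mlk = _person_records([("A1", 2005, None), ("A2", 2008, None)])
    adm.loc[adm["record_id"] == "A2", "birth_date"] = T(1940, 2, 2)  # distinct keys
    rep = person_slk_most_recent(adm, mlk)
    keyed = with_slk(adm, "separation_date").set_index("record_id")["slk"]
    assert rep["P1"] == keyed["A2"]


def test_most_frequent_picks_modal_complete_key():
    adm, mlk = _person_records(
        [("A1", 2004, "Taylor"), ("A2", 2005, "Taylor"), ("A3", 2008, "Brown")]
    )
    rep = person_slk_most_frequent(adm, mlk)
    keyed = with_slk(adm, "separation_date").set_index("record_id")["slk"]
    assert rep["P1"] == keyed["A1"]  # Taylor twice beats Brown once


def test_most_frequent_breaks_ties_by_recency():
    adm, mlk = _person_records([("A1", 2005, "Taylor"), ("A2", 2008, "Brown")])
    rep = person_slk_most_frequent(adm, mlk)
    keyed = with_slk(adm, "separation_date").set_index("record_id")["slk"]
    assert rep["P1"] == keyed["A2"]


def test_most_frequent_uses_modal_incomplete_when_no_complete_exists():
    adm, mlk = _person_records(
        [("A1", 2004, None), ("A2", 2005, None), ("A3", 2008, None)]
    )
    adm.loc[adm["record_id"] == "A3", "birth_date"] = T(1940, 2, 2)
    rep = person_slk_most_frequent(adm, mlk)
    keyed = with_slk(adm, "separation_date").set_index("record_id")["slk"]
    assert rep["P1"] == keyed["A1"]  # the A1/A2 key occurs twice


def test_link_via_person_slk_unions_and_flags_shared_keys():
    # P1 and P2 share an identical representative identity
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions(
        [
            {"record_id": "A1"},
            {"record_id": "A2", "true_id": "P2"},
            {"record_id": "A3", "true_id": "P2"},
        ]
    )
    mlk = make_mlk([("D1", "P1"), ("A1", "P1"), ("A2", "P2"), ("A3", "P2")])
    rep = person_slk_most_recent(adm, mlk)
    res = link_via_person_slk(deaths, rep, adm, mlk)
    assert res.links["D1"] == frozenset({"A1", "A2", "A3"})
    assert res.ambiguous == frozenset({"D1"})


def test_link_via_person_slk_no_matching_person():
    deaths = make_deaths([{"record_id": "D1", "surname": "Zed"}])
    adm = make_admissions([{"record_id": "A1"}])
    mlk = make_mlk([("D1", "P1"), ("A1", "P1")])
    rep = person_slk_most_recent(adm, mlk)
    assert link_via_person_slk(deaths, rep, adm, mlk).links["D1"] == frozenset()


# -- strategy 5: any match ---------------------------------------------------


def test_any_match_expands_slk_hits_to_full_person_groups():
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions(
        [
            {"record_id": "A1"},  # SLK hit
            {"record_id": "A2", "surname": None, "given_name": None},  # same person, no hit
            {"record_id": "A3", "surname": "Brown"},  # same person, different key
        ]
    )
    mlk = make_mlk([("D1", "P1"), ("A1", "P1"), ("A2", "P1"), ("A3", "P1")])
    res = link_any_match(deaths, adm, mlk)
    assert res.links["D1"] == frozenset({"A1", "A2", "A3"})


def test_any_match_empty_stage_one_stays_empty():
    deaths = make_deaths([{"record_id": "D1", "surname": "Zed"}])
    adm = make_admissions([{"record_id": "A1"}])
    mlk = make_mlk([("D1", "P1"), ("A1", "P1")])
    assert link_any_match(deaths, adm, mlk).links["D1"] == frozenset()


def test_any_match_union_of_two_matched_persons_is_flagged():
    deaths = make_deaths([{"record_id": "D1"}])
    adm = make_admissions(
        [
            {"record_id": "A1"},
            {"record_id": "A2", "true_id": "P2"},
            {"record_id": "A3", "true_id": "P2", "surname": "Brown"},
        ]
    )
    mlk = make_mlk([("D1", "P1"), ("A1", "P1"), ("A2", "P2"), ("A3", "P2")])
    res = link_any_match(deaths, adm, mlk)
    assert res.links["D1"] == frozenset({"A1", "A2", "A3"})
    assert res.ambiguous == frozenset({"D1"})


def test_unknown_strategy_name_rejected():
    with pytest.raises(DataError, match="unknown strategy"):
        run_strategy("fuzzy", make_deaths([{"record_id": "D1"}]),
                     make_admissions([{"record_id": "A1"}]),
                     make_mlk([("D1", "P1"), ("A1", "P1")]))


# -- structural properties on generated studies ------------------------------


def test_any_match_is_superset_of_basic_per_death(default_sim):
    basic = default_sim["results"][BASIC]
    anym = default_sim["results"][ANY_MATCH]
    for rid in basic.links:
        assert anym.links[rid] >= basic.links[rid]


def test_linked_death_counts_agree_between_basic_and_any_match(default_sim):
    basic = default_sim["results"][BASIC]
    anym = default_sim["results"][ANY_MATCH]
    assert basic.linked_deaths == anym.linked_deaths


def test_zero_noise_collapses_all_strategies(noise_free_sim):
    results = noise_free_sim["results"]
    reference = results[FULL_PROBABILISTIC]
    for name in STRATEGIES:
        assert results[name].links == reference.links, name


def test_perfect_mlk_any_match_missed_persons_subset_of_basic(default_sim):
    """With the true grouping as both MLK and reference, persons missed
    by any-match are a subset of those missed by basic SLK."""
    adm, deaths = default_sim["admissions"], default_sim["deaths"]
    mlk_true = default_sim["mlk_true"]
    retained = dedupe_deaths(deaths, mlk_true, 7)
    ref = link_full_probabilistic(retained, adm, mlk_true)
    basic = link_basic_slk(retained, adm)
    anym = link_any_match(retained, adm, mlk_true)
    missed_basic = {d for d, r in ref.links.items() if r - basic.links[d]}
    missed_any = {d for d, r in ref.links.items() if r - anym.links[d]}
    assert missed_any <= missed_basic


def test_hash_join_matches_brute_force_all_pairs():
    """SLK matching through the grouped join equals the O(n^2)
    definition on a small instance."""
    cfg_rows = []
    rng = np.random.default_rng(8)
    surnames = ["Taylor", "Brown", "Ng", None, "O'Brien"]
    givens = ["Lee", "Ann", None, "Kim"]
    for i in range(300):
        cfg_rows.append(
            {
                "record_id": f"A{i:03d}",
                "surname": surnames[rng.integers(len(surnames))],
                "given_name": givens[rng.integers(len(givens))],
                "birth_date": T(1940 + int(rng.integers(3)), 6, 15),
                "sex": ["male", "female"][rng.integers(2)],
            }
        )
    adm = make_admissions(cfg_rows)
    deaths = make_deaths(
        [
            {
                "record_id": f"D{i:02d}",
                "surname": surnames[rng.integers(len(surnames))],
                "given_name": givens[rng.integers(len(givens))],
                "birth_date": T(1940 + int(rng.integers(3)), 6, 15),
                "sex": ["male", "female"][rng.integers(2)],
            }
            for i in range(60)
        ]
    )
    res = link_basic_slk(deaths, adm)
    adm_k = with_slk(adm, "separation_date")
    dth_k = with_slk(deaths, "death_date")
    for _, drow in dth_k.iterrows():
        brute = frozenset(
            arow["record_id"]
            for _, arow in adm_k.iterrows()
            if arow["slk"] == drow["slk"]
        )
        assert res.links[drow["record_id"]] == brute
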