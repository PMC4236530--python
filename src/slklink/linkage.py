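"""The five record-linkage strategies over admissions, deaths and an MLK.

Each strategy links every retained death record to a (possibly empty)
set of hospital-admission records:

1. ``full_probabilistic`` — follow the supplied master linkage key
   (MLK) person grouping exactly; this is the reference standard.
2. ``basic_slk`` — exact equality of the full 14-character SLK-581,
   dummy characters included; the MLK is not used.
3. ``most_recent_slk`` — each MLK person is represented by the SLK-581
   of their most recent separation, preferring complete keys over
   recency; deaths match persons by that representative key and link
   to all the person's admissions.
4. ``most_frequent_slk`` — as above, but the representative key is the
   person's modal complete SLK-581 (ties to the most recent bearer;
   incomplete keys only when no complete one exists).
5. ``any_match_slk`` — two stages: match by SLK-581 as in strategy 2,
   then expand every matched record to its full MLK person group; the
   result is by construction a superset of the basic match.

Matching is exact string equality of the whole key: an all-dummy name
block (``"99999"``) only ever matches another record missing both
names, which is what keeps false-positive rates low even when
missingness is heavy.  A death whose key matches more than one MLK
person links to the union of their records and is flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .slk581 import add_slk_columns
from .synth import STREAM_DEDUPE

__all__ = [
    "STRATEGIES",
    "LinkageResult",
    "with_slk",
    "dedupe_deaths",
    "link_full_probabilistic",
    "link_basic_slk",
    "person_slk_most_recent",
    "person_slk_most_frequent",
    "link_via_person_slk",
    "link_any_match",
    "run_strategy",
    "run_all_strategies",
]

FULL_PROBABILISTIC = "full_probabilistic"
BASIC = "basic_slk"
MOST_RECENT = "most_recent_slk"
MOST_FREQUENT = "most_frequent_slk"
ANY_MATCH = "any_match_slk"
STRATEGIES = (FULL_PROBABILISTIC, BASIC, MOST_RECENT, MOST_FREQUENT, ANY_MATCH)


@dataclass
class LinkageResult:
    """Per-death linked admission sets under one strategy.

    ``links`` maps every retained death record id to a frozenset of
    admission record ids (possibly empty).  ``ambiguous`` holds death
    ids whose SLK matched more than one MLK person.
    """

    strategy: str
    links: dict = field(default_factory=dict)
    ambiguous: frozenset = frozenset()

    @property
    def linked_deaths(self) -> int:
        return sum(1 for s in self.links.values() if s)

    @property
    def unlinked_deaths(self) -> int:
        return len(self.links) - self.linked_deaths

    @property
    def n_linked_admissions(self) -> int:
        seen: set = set()
        for s in self.links.values():
            seen |= s
        return len(seen)

    def summary(self) -> dict:
        n = len(self.links)
        return {
            "strategy": self.strategy,
            "deaths": n,
            "deaths_linked": self.linked_deaths,
            "deaths_unlinked": self.unlinked_deaths,
            "pct_unlinked": round(100.0 * self.unlinked_deaths / n, 1) if n else 0.0,
            "admission_records_linked": self.n_linked_admissions,
            "ambiguous_deaths": len(self.ambiguous),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "death_record_id": d,
                "admission_record_id": a,
                "strategy": self.strategy,
                "ambiguous_flag": d in self.ambiguous,
            }
            for d in sorted(self.links)
            for a in sorted(self.links[d])
        ]
        return pd.DataFrame(
            rows,
            columns=["death_record_id", "admission_record_id", "strategy", "ambiguous_flag"],
        )


def with_slk(df: pd.DataFrame, event_col: str) -> pd.DataFrame:
    """Ensure a frame carries SLK columns (no-op if already present)."""
    if "slk" in df.columns:
        return df
    return add_slk_columns(df, event_col=event_col)


def _person_key_map(mlk: pd.DataFrame, record_ids, what: str) -> pd.Series:
    keys = mlk.set_index("record_id")["person_key"]
    missing = set(record_ids) - set(keys.index)
    if missing:
        rid = sorted(missing)[0]
        raise DataError(f"{what} record id {rid!r} absent from the MLK")
    return keys

def _admission_groups(admissions: pd.DataFrame, mlk: pd.DataFrame) -> dict:
    """person_key -> frozenset of admission record ids."""
    keys = _person_key_map(mlk, admissions["record_id"], "admission")
    pk = admissions["record_id"].map(keys)
    return {
        k: frozenset(v)
        for k, v in admissions.groupby(pk.to_numpy())["record_id"].agg(list).items()
    }


def dedupe_deaths(deaths: pd.DataFrame, mlk: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Retain exactly one death record per MLK person.

    Duplicate registrations are resolved by a uniform random draw,
    deterministic given ``seed``; the same retained set must then feed
    every strategy.
    """
    if deaths.empty:
        return deaths.copy()
    keys = _person_key_map(mlk, deaths["record_id"], "death")
    d = deaths.sort_values("record_id").reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STREAM_DEDUPE]))
    d["_draw"] = rng.random(len(d))
    d["_pk"] = d["record_id"].map(keys)
    keep = d.loc[d.groupby("_pk")["_draw"].idxmax()]
    return (
        keep.drop(columns=["_draw", "_pk"])
        .sort_values("record_id")
        .reset_index(drop=True)
    )


def link_full_probabilistic(
    deaths: pd.DataFrame, admissions: pd.DataFrame, mlk: pd.DataFrame
) -> LinkageResult:
    """Strategy 1: follow the MLK person grouping (the reference)."""
    groups = _admission_groups(admissions, mlk)
    death_keys = _person_key_map(mlk, deaths["record_id"], "death")
    links = {
        rid: groups.get(death_keys[rid], frozenset()) for rid in deaths["record_id"]
    }
    return LinkageResult(FULL_PROBABILISTIC, links)


def link_basic_slk(deaths: pd.DataFrame, admissions: pd.DataFrame) -> LinkageResult:
    """Strategy 2: exact 14-character SLK-581 equality, nothing else."""
    deaths = with_slk(deaths, "death_date")
    admissions = with_slk(admissions, "separation_date")
    by_slk = {
        k: frozenset(v) for k, v in admissions.groupby("slk")["record_id"].agg(list).items()
    }
    links = {
        rid: by_slk.get(slk, frozenset())
        for rid, slk in zip(deaths["record_id"], deaths["slk"])
    }
    return LinkageResult(BASIC, links)


def person_slk_most_recent(admissions: pd.DataFrame, mlk: pd.DataFrame) -> pd.Series:
    """Representative SLK per MLK person: most recent separation's key,
    preferring complete keys; the most recent incomplete key only when
    the person has no complete one.  Date ties break to the largest
    record id.  Returns a Series indexed by person_key.
    """
    adm = with_slk(admissions, "separation_date")
    keys = _person_key_map(mlk, adm["record_id"], "admission")
    work = adm.assign(_pk=adm["record_id"].map(keys))
    work = work.sort_values(["slk_complete", "separation_date", "record_id"])
    rep = work.groupby("_pk").tail(1)
    return rep.set_index("_pk")["slk"]


def person_slk_most_frequent(admissions: pd.DataFrame, mlk: pd.DataFrame) -> pd.Series:
    """Representative SLK per MLK person: the modal complete key; ties
    break to the key on the most recent separation (then largest record
    id); incomplete keys are used only when no complete one exists."""
    adm = with_slk(admissions, "separation_date")
    keys = _person_key_map(mlk, adm["record_id"], "admission")
    work = adm.assign(_pk=adm["record_id"].map(keys))
    has_complete = work.groupby("_pk")["slk_complete"].transform("any")
    work = work[work["slk_complete"] | ~has_complete]
    per_key = (
        work.sort_values(["separation_date", "record_id"])
        .groupby(["_pk", "slk"])
        .agg(
            _n=("record_id", "size"),
            _last_date=("separation_date", "last"),
            _last_rid=("record_id", "last"),
        )
        .reset_index()
    )
    rep = (
        per_key.sort_values(["_pk", "_n", "_last_date", "_last_rid"])
        .groupby("_pk")
        .tail(1)
    )
    return rep.set_index("_pk")["slk"]


def link_via_person_slk(
    deaths: pd.DataFrame,
    slk_map: pd.Series,
    admissions: pd.DataFrame,
    mlk: pd.DataFrame,
    strategy: str = MOST_RECENT,
) -> LinkageResult:
    """Strategies 3/4 linkage step: a death matches every MLK person
    whose representative key equals its own key; it links to the union
    of the matched persons' admissions and is flagged ambiguous when
    more than one person matched."""
    deaths = with_slk(deaths, "death_date")
    groups = _admission_groups(admissions, mlk)
    inverse: dict = {}
    for pk, slk in slk_map.items():
        inverse.setdefault(slk, []).append(pk)
    links = {}
    ambiguous = set()
    for rid, slk in zip(deaths["record_id"], deaths["slk"]):
        persons = inverse.get(slk, ())
        linked: frozenset = frozenset()
        for pk in persons:
            linked |= groups.get(pk, frozenset())
        links[rid] = linked
        if len(persons) > 1:
            ambiguous.add(rid)
    return LinkageResult(strategy, links, frozenset(ambiguous))


def link_any_match(
    deaths: pd.DataFrame, admissions: pd.DataFrame, mlk: pd.DataFrame
) -> LinkageResult:
    """Strategy 5: SLK match first, then expand each matched admission
    to its full MLK person group (admissions only)."""
    stage1 = link_basic_slk(deaths, admissions)
    rec_keys = _person_key_map(mlk, admissions["record_id"], "admission")
    groups = _admission_groups(admissions, mlk)
    links = {}
    ambiguous = set()
    for rid, hits in stage1.links.items():
        persons = {rec_keys[a] for a in hits}
        linked: frozenset = frozenset()
        for pk in persons:
            linked |= groups[pk]
        links[rid] = linked
        if len(persons) > 1:
            ambiguous.add(rid)
    return LinkageResult(ANY_MATCH, links, frozenset(ambiguous))


def run_strategy(
    strategy: str, deaths: pd.DataFrame, admissions: pd.DataFrame, mlk: pd.DataFrame
) -> LinkageResult:
    """Dispatch one strategy by name over prepared (deduplicated) deaths."""
    if strategy == FULL_PROBABILISTIC:
        return link_full_probabilistic(deaths, admissions, mlk)
    if strategy == BASIC:
        return link_basic_slk(deaths, admissions)
    if strategy == MOST_RECENT:
        slk_map = person_slk_most_recent(admissions, mlk)
        return link_via_person_slk(deaths, slk_map, admissions, mlk, MOST_RECENT)
    if strategy == MOST_FREQUENT:
        slk_map = person_slk_most_frequent(admissions, mlk)
        return link_via_person_slk(deaths, slk_map, admissions, mlk, MOST_FREQUENT)
    if strategy == ANY_MATCH:
        return link_any_match(deaths, admissions, mlk)
    raise DataError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def run_all_strategies(
    deaths: pd.DataFrame,
    admissions: pd.DataFrame,
    mlk: pd.DataFrame,
    strategies=STRATEGIES,
) -> dict:
    """Run the selected strategies over one shared prepared dataset."""
    deaths = with_slk(deaths, "death_date")
    admissions = with_slk(admissions, "separation_date")
    return {s: run_strategy(s, deaths, admissions, mlk) for s in strategies}
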