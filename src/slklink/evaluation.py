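"""Evaluation of linkage strategies against the probabilistic reference.

Takes per-death linked admission sets (``LinkageResult``) and computes:

* per-person missed-link / false-positive-link indicators and rates,
  with the full-probabilistic strategy as the standard — a missed link
  is a reference-linked record the strategy failed to link, a false
  positive one the strategy linked but the reference did not; one
  person can have both at once;
* the error trend across financial years of admission;
* health-service-utilisation statistics per look-back window of
  financial years ending at the death year: percentage of decedents
  hospitalised, mean hospitalisations with a normal-approximation 95%
  confidence interval, median and quartiles — all over every retained
  death record, counting the unlinked as zero;
* condition-specific hospitalisation rates and their rate ratio versus
  the reference (ratio 1.00 means no under-ascertainment).

Windows are spans of financial years (1 July - 30 June), identified by
their July starting year: ``(2000, 2008)`` is the nine-year window
labelled ``2000-01 to 2008-09``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .linkage import FULL_PROBABILISTIC, LinkageResult

__all__ = [
    "financial_year",
    "fy_label",
    "window_label",
    "default_windows",
    "LinkComparison",
    "compare_links",
    "error_trend_by_year",
    "percent_hospitalised",
    "UtilisationStats",
    "hospitalisation_stats",
    "condition_rates",
    "table_percent_hospitalised",
    "table_mean_hospitalisations",
    "table_median_hospitalisations",
    "table_condition_rates",
    "error_trend_table",
    "plot_error_trends",
]

Z_95 = 1.96  # normal-approximation 95% CI multiplier


def financial_year(d) -> int:
    """July-June financial year of a date, named by its starting year."""
    ts = pd.Timestamp(d)
    return ts.year if ts.month >= 7 else ts.year - 1


def fy_label(fy: int) -> str:
    return f"{fy}-{(fy + 1) % 100:02d}"


def window_label(window: tuple) -> str:
    lo, hi = window
    return fy_label(lo) if lo == hi else f"{fy_label(lo)} to {fy_label(hi)}"


def default_windows(end_fy: int = 2008, n_years: int = 9) -> list:
    """Look-back windows of 1..n financial years all ending at end_fy."""
    return [(end_fy - k, end_fy) for k in range(n_years)]


@dataclass
class LinkComparison:
    """Person-level linkage-error assessment of one strategy."""

    strategy: str
    per_death: pd.DataFrame  # death_record_id, missed_any, false_any
    missed_rate: float  # proportion of persons with >=1 missed link
    fp_rate: float  # proportion of persons with >=1 false positive link
    n_reference_linked: int  # denominator: deaths with >=1 reference link


def _check_same_deaths(result: LinkageResult, reference: LinkageResult) -> None:
    if set(result.links) != set(reference.links):
        raise DataError(
            "strategy and reference cover different retained death records"
        )


def compare_links(result: LinkageResult, reference: LinkageResult) -> LinkComparison:
    """Per-person missed / false-positive assessment vs the reference.

    Rates are proportions over retained deaths with at least one
    reference-linked record (a person the reference never linked can
    have no missed link).
    """
    _check_same_deaths(result, reference)
    rows = []
    for rid, ref_set in reference.links.items():
        s = result.links[rid]
        rows.append(
            {
                "death_record_id": rid,
                "missed_any": bool(ref_set - s),
                "false_any": bool(s - ref_set),
                "reference_linked": bool(ref_set),
            }
        )
    per_death = pd.DataFrame(rows)
    denom = per_death[per_death["reference_linked"]]
    n = len(denom)
    return LinkComparison(
        strategy=result.strategy,
        per_death=per_death.drop(columns="reference_linked"),
        missed_rate=float(denom["missed_any"].mean()) if n else 0.0,
        fp_rate=float(denom["false_any"].mean()) if n else 0.0,
        n_reference_linked=n,
    )


def _admission_fy(admissions: pd.DataFrame) -> dict:
    return {
        rid: financial_year(d)
        for rid, d in zip(admissions["record_id"], admissions["separation_date"])
    }


def error_trend_by_year(
    result: LinkageResult, reference: LinkageResult, admissions: pd.DataFrame
) -> pd.DataFrame:
    """Missed / false-positive person rates per financial year of the
    admission records involved.

    For year ``y``, the denominator is decedents with at least one
    reference-linked record separated in ``y``; a decedent counts as
    missed in ``y`` when some reference record of theirs dated ``y`` is
    not in the strategy's set, and as false-positive in ``y`` when the
    strategy links them a record dated ``y`` outside their reference
    set.
    """
    _check_same_deaths(result, reference)
    fy_of = _admission_fy(admissions)
    years = sorted({fy_of[a] for s in reference.links.values() for a in s}
                   | {fy_of[a] for s in result.links.values() for a in s})
    rows = []
    for y in years:
        denom = missed = false = 0
        for rid, ref_set in reference.links.items():
            s = result.links[rid]
            ref_y = {a for a in ref_set if fy_of[a] == y}
            if ref_y:
                denom += 1
                if ref_y - s:
                    missed += 1
                if any(fy_of[a] == y for a in s - ref_set):
                    false += 1
        rows.append(
            {
                "fin_year": y,
                "fin_year_label": fy_label(y),
                "strategy": result.strategy,
                "n_persons": denom,
                "missed_rate": missed / denom if denom else 0.0,
                "fp_rate": false / denom if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _counts_in_window(
    result: LinkageResult, retained_deaths: pd.DataFrame, admissions: pd.DataFrame,
    window: tuple,
) -> np.ndarray:
    """Linked-admission counts per retained death, zeros included."""
    lo, hi = window
    fy_of = _admission_fy(admissions)
    out = np.zeros(len(retained_deaths), dtype=int)
    for i, rid in enumerate(retained_deaths["record_id"]):
        if rid not in result.links:
            raise DataError(f"death record {rid!r} missing from linkage result")
        out[i] = sum(1 for a in result.links[rid] if lo <= fy_of[a] <= hi)
    return out


def percent_hospitalised(
    result: LinkageResult,
    retained_deaths: pd.DataFrame,
    admissions: pd.DataFrame,
    window: tuple,
) -> float:
    """Percentage of retained deaths with >=1 linked admission separated
    within the window.  The denominator is every retained death record,
    unlinked persons included."""
    if retained_deaths.empty:
        raise DataError("no retained deaths")
    counts = _counts_in_window(result, retained_deaths, admissions, window)
    return float(100.0 * (counts > 0).mean())


@dataclass
class UtilisationStats:
    """Hospitalisations per decedent over one look-back window."""

    window: tuple
    n: int
    percent_hospitalised: float
    mean: float
    ci95: tuple
    median: float
    q25: float
    q75: float


def hospitalisation_stats(
    result: LinkageResult,
    retained_deaths: pd.DataFrame,
    admissions: pd.DataFrame,
    window: tuple,
) -> UtilisationStats:
    """Mean (with normal-approximation 95% CI), median and quartiles of
    linked hospitalisations per retained death within the window,
    counting unlinked deaths as zero."""
    if retained_deaths.empty:
        raise DataError("no retained deaths")
    counts = _counts_in_window(result, retained_deaths, admissions, window)
    n = len(counts)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n > 1 else 0.0
    half = Z_95 * sd / np.sqrt(n) if n else 0.0
    q25, med, q75 = (float(q) for q in np.percentile(counts, [25, 50, 75]))
    return UtilisationStats(
        window=window,
        n=n,
        percent_hospitalised=float(100.0 * (counts > 0).mean()),
        mean=mean,
        ci95=(mean - half, mean + half),
        median=med,
        q25=q25,
        q75=q75,
    )


def condition_rates(
    results: dict,
    retained_deaths: pd.DataFrame,
    admissions: pd.DataFrame,
    window: tuple,
    reference: str = FULL_PROBABILISTIC,
    conditions=None,
) -> pd.DataFrame:
    """Condition-specific hospitalisation rates and rate ratios.

    Per condition and strategy: the percentage of retained deaths with
    at least one linked in-window admission carrying the condition
    label, and its ratio (2 d.p.) to the reference strategy's rate.
    """
    if reference not in results:
        raise DataError(f"reference strategy {reference!r} missing from results")
    adm = admissions.fillna({"conditions": ""})
    labels_per_record = {
        rid: frozenset(c for c in str(conds).split(";") if c)
        for rid, conds in zip(adm["record_id"], adm["conditions"])
    }
    known = sorted({c for s in labels_per_record.values() for c in s})
    if conditions is None:
        conditions = known
    else:
        unknown = sorted(set(conditions) - set(known))
        if unknown:
            raise DataError(f"unknown condition label {unknown[0]!r}")
    lo, hi = window
    fy_of = _admission_fy(admissions)

    def rate(result: LinkageResult, label: str) -> float:
        hit = 0
        for rid in retained_deaths["record_id"]:
            if any(
                lo <= fy_of[a] <= hi and label in labels_per_record[a]
                for a in result.links[rid]
            ):
                hit += 1
        return 100.0 * hit / len(retained_deaths)

    ref_rates = {c: rate(results[reference], c) for c in conditions}
    rows = []
    for strategy, result in results.items():
        for c in conditions:
            r = ref_rates[c] if strategy == reference else rate(result, c)
            ratio = r / ref_rates[c] if ref_rates[c] else np.nan
            rows.append(
                {
                    "condition": c,
                    "strategy": strategy,
                    "rate_pct": round(r, 1),
                    "rate_ratio": round(ratio, 2) if np.isfinite(ratio) else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report tables (published layout: windows x strategies)


def _window_frame(results, retained_deaths, admissions, windows, value_fn) -> pd.DataFrame:
    rows = []
    for window in windows:
        row = {"window": window_label(window)}
        for strategy, result in results.items():
            row.update(value_fn(strategy, result, window))
        rows.append(row)
    return pd.DataFrame(rows)


def table_percent_hospitalised(
    results: dict, retained_deaths: pd.DataFrame, admissions: pd.DataFrame, windows
) -> pd.DataFrame:
    """Percentage hospitalised by look-back window and strategy (1 d.p.)."""

    def cell(strategy, result, window):
        pct = percent_hospitalised(result, retained_deaths, admissions, window)
        return {strategy: round(pct, 1)}

    return _window_frame(results, retained_deaths, admissions, windows, cell)


def table_mean_hospitalisations(
    results: dict, retained_deaths: pd.DataFrame, admissions: pd.DataFrame, windows
) -> pd.DataFrame:
    """Mean hospitalisations (95% CI bounds) by window and strategy."""

    def cell(strategy, result, window):
        st = hospitalisation_stats(result, retained_deaths, admissions, window)
        return {
            f"{strategy}_mean": round(st.mean, 1),
            f"{strategy}_ci_lo": round(st.ci95[0], 1),
            f"{strategy}_ci_hi": round(st.ci95[1], 1),
        }

    return _window_frame(results, retained_deaths, admissions, windows, cell)


def table_median_hospitalisations(
    results: dict, retained_deaths: pd.DataFrame, admissions: pd.DataFrame, windows
) -> pd.DataFrame:
    """Median (25th, 75th percentile) hospitalisations by window and strategy."""

    def cell(strategy, result, window):
        st = hospitalisation_stats(result, retained_deaths, admissions, window)
        return {
            f"{strategy}_median": st.median,
            f"{strategy}_q25": st.q25,
            f"{strategy}_q75": st.q75,
        }

    return _window_frame(results, retained_deaths, admissions, windows, cell)


def table_condition_rates(
    results: dict,
    retained_deaths: pd.DataFrame,
    admissions: pd.DataFrame,
    window: tuple,
    reference: str = FULL_PROBABILISTIC,
) -> pd.DataFrame:
    """Condition rates and rate ratios pivoted to condition rows."""
    tidy = condition_rates(results, retained_deaths, admissions, window, reference)
    wide = tidy.pivot(index="condition", columns="strategy",
                      values=["rate_pct", "rate_ratio"])
    return wide


def error_trend_table(
    results: dict, reference_result: LinkageResult, admissions: pd.DataFrame
) -> pd.DataFrame:
    """Stacked per-year missed/false rates for all non-reference strategies."""
    parts = [
        error_trend_by_year(result, reference_result, admissions)
        for name, result in results.items()
        if name != reference_result.strategy
    ]
    if not parts:
        return pd.DataFrame(
            columns=["fin_year", "fin_year_label", "strategy",
                     "n_persons", "missed_rate", "fp_rate"]
        )
    return pd.concat(parts, ignore_index=True)


def plot_error_trends(trend: pd.DataFrame, path, value: str = "missed_rate") -> None:
    """Render a per-year error-rate series per strategy to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for strategy, grp in trend.groupby("strategy"):
        grp = grp.sort_values("fin_year")
        ax.plot(grp["fin_year_label"], 100 * grp[value], marker="o", label=strategy)
    ax.set_xlabel("financial year of admission")
    ax.set_ylabel(f"% of persons ({value.replace('_', ' ')})")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
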