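"""Outcome measures and scenario comparisons.

For each scenario the cohort run is summarized into: an age-adjusted
dementia incidence rate, an age-adjusted prevalence, total dementia cases,
and life years lived with and without dementia, plus the same quantities by
single year of age and the lifetime risk of dementia at 65.  Comparisons
against the reference scenario report percent changes, by-age absolute
differences, by-age differences per 100,000 life years lived (which adjust
for the larger surviving population under risk reduction), and the
crossover age at which postponed cases start to exceed prevented ones.

Age standardization uses the *reference scenario's* person-year
distribution by age, so the reference's adjusted rates equal its crude
rates and scenario contrasts are isolated from the population-structure
shift the scenarios themselves induce.  Dementia states are mild, moderate
and severe; MCI counts as dementia-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .cohort import CohortResult, lifetime_risk

#: scale of the reported incidence rate (events per this many person-years)
INCIDENCE_SCALE = 100.0
PER_100K = 100_000.0


@dataclass
class OutcomeReport:
    """All reported outcomes for one scenario and sex.

    ``age_adjusted_incidence`` is in events per ``incidence_scale``
    person-years at risk and ``age_adjusted_prevalence`` in percent;
    absolute outcomes are per simulated cohort of size ``n``.
    """

    sex: str
    scenario: str
    n: float
    age_adjusted_incidence: float
    age_adjusted_prevalence: float
    total_cases: float
    ly_with_dementia: float
    ly_without_dementia: float
    lifetime_risk_65: float
    incidence_scale: float
    by_age_cases: np.ndarray
    by_age_ly_with: np.ndarray
    by_age_ly_without: np.ndarray
    by_age_py_alive: np.ndarray

    _SCALAR_OUTCOMES = (
        "age_adjusted_incidence",
        "age_adjusted_prevalence",
        "total_cases",
        "ly_with_dementia",
        "ly_without_dementia",
        "lifetime_risk_65",
    )

    def scalar_outcomes(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._SCALAR_OUTCOMES}


def reference_weights(result: CohortResult) -> np.ndarray:
    """Age-standardization weights: the run's alive person-year shares."""
    py = result.py_alive_by_age()
    return py / py.sum()


def summarize(
    result: CohortResult,
    standard: "CohortResult | np.ndarray | None" = None,
    from_age_lifetime: int = 65,
    incidence_scale: float = INCIDENCE_SCALE,
) -> OutcomeReport:
    """Summarize a cohort run into the reported outcome set.

    ``standard`` fixes the age-standardization: pass the reference
    scenario's :class:`CohortResult` so the incidence rate is weighted by
    the reference's at-risk person-year shares and the prevalence by its
    alive person-year shares (the reference's own adjusted rates then equal
    its crude rates); an explicit weight vector applies to both rates; the
    default standardizes the run by itself.
    """
    A = result.max_age
    if standard is None:
        standard = result
    if isinstance(standard, CohortResult):
        if standard.max_age != A:
            raise ValueError("standard covers a different age range")
        w_inc = standard.py_at_risk_by_age(result.incidence_event)
        w_prev = standard.py_alive_by_age()
    else:
        w_inc = w_prev = np.asarray(standard, dtype=float)
        if w_inc.shape != (A + 1,):
            raise ValueError(f"weights length {w_inc.shape} does not match ages 0..{A}")
    w_inc = w_inc / w_inc.sum()
    w_prev = w_prev / w_prev.sum()

    onsets = result.onsets().sum(axis=1)
    at_risk = result.py_at_risk_by_age()
    py_alive = result.py_alive_by_age()
    py_dem = result.py_dementia_by_age()

    with np.errstate(invalid="ignore", divide="ignore"):
        inc_rate = np.where(at_risk > 0, onsets / np.where(at_risk > 0, at_risk, 1.0), 0.0)
        prev_rate = np.where(py_alive > 0, py_dem / np.where(py_alive > 0, py_alive, 1.0), 0.0)
    adj_inc = float(w_inc @ inc_rate) * incidence_scale
    adj_prev = float(w_prev @ prev_rate) * 100.0

    ly_with = float(py_dem.sum())
    ly_without = float(result.py_dementia_free_by_age().sum())
    lr = (
        lifetime_risk(result, from_age_lifetime)
        if from_age_lifetime <= A
        else float("nan")
    )
    return OutcomeReport(
        sex=result.sex,
        scenario=result.scenario,
        n=result.n,
        age_adjusted_incidence=adj_inc,
        age_adjusted_prevalence=adj_prev,
        total_cases=float(onsets.sum()),
        ly_with_dementia=ly_with,
        ly_without_dementia=ly_without,
        lifetime_risk_65=lr,
        incidence_scale=incidence_scale,
        by_age_cases=onsets,
        by_age_ly_with=py_dem,
        by_age_ly_without=result.py_dementia_free_by_age(),
        by_age_py_alive=py_alive,
    )


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def crossover_age(diff: np.ndarray, smooth_window: int = 5) -> float | None:
    """Smallest age at which a by-age difference becomes and stays >= 0.

    The difference curve is smoothed with a centered moving average to
    suppress Monte-Carlo flicker near zero.  Returns ``None`` when the
    curve never dips below zero (no postponement signal) or never settles
    at or above zero.
    """
    d = moving_average(np.asarray(diff, dtype=float), smooth_window)
    nonneg = d >= 0
    if nonneg.all() or not nonneg[-1]:
        return None
    # last index where the curve is negative; crossover is the next age
    last_neg = np.max(np.nonzero(~nonneg))
    if last_neg + 1 >= len(d):
        return None
    return float(last_neg + 1)


@dataclass
class ScenarioComparison:
    """A scenario's outcomes relative to the reference scenario."""

    sex: str
    scenario: str
    pct_change: dict[str, float]
    by_age_cases_diff: np.ndarray
    by_age_ly_with_diff: np.ndarray
    by_age_ly_without_diff: np.ndarray
    per_100k_cases_diff: np.ndarray
    per_100k_ly_with_diff: np.ndarray
    per_100k_ly_without_diff: np.ndarray
    crossover_age_cases: float | None
    crossover_age_cases_raw: float | None
    crossover_age_ly: float | None
    lifetime_risk_65: float
    lifetime_risk_65_ref: float


def compare(ref: OutcomeReport, alt: OutcomeReport) -> ScenarioComparison:
    """Compare a scenario's outcome report against the reference's.

    Both reports must come from cohorts of the same sex and size,
    summarized with the same weights.
    """
    if ref.sex != alt.sex:
        raise ValueError("comparing reports of different sexes")
    if ref.n != alt.n:
        raise ValueError("comparing reports of different cohort sizes")
    pct = {}
    for k, rv in ref.scalar_outcomes().items():
        av = alt.scalar_outcomes()[k]
        if rv == 0:
            if av != 0:
                raise ZeroDivisionError(f"reference outcome {k} is zero")
            pct[k] = 0.0
        else:
            pct[k] = 100.0 * (av - rv) / rv

    cases_diff = alt.by_age_cases - ref.by_age_cases
    ly_with_diff = alt.by_age_ly_with - ref.by_age_ly_with
    ly_without_diff = alt.by_age_ly_without - ref.by_age_ly_without

    def per_100k(alt_x, ref_x):
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = np.where(alt.by_age_py_alive > 0, alt_x / np.where(alt.by_age_py_alive > 0, alt.by_age_py_alive, 1.0), 0.0)
            rr = np.where(ref.by_age_py_alive > 0, ref_x / np.where(ref.by_age_py_alive > 0, ref.by_age_py_alive, 1.0), 0.0)
        return (ra - rr) * PER_100K

    return ScenarioComparison(
        sex=ref.sex,
        scenario=alt.scenario,
        pct_change=pct,
        by_age_cases_diff=cases_diff,
        by_age_ly_with_diff=ly_with_diff,
        by_age_ly_without_diff=ly_without_diff,
        per_100k_cases_diff=per_100k(alt.by_age_cases, ref.by_age_cases),
        per_100k_ly_with_diff=per_100k(alt.by_age_ly_with, ref.by_age_ly_with),
        per_100k_ly_without_diff=per_100k(alt.by_age_ly_without, ref.by_age_ly_without),
        crossover_age_cases=crossover_age(cases_diff),
        crossover_age_cases_raw=crossover_age(cases_diff, smooth_window=1),
        crossover_age_ly=crossover_age(ly_with_diff),
        lifetime_risk_65=alt.lifetime_risk_65,
        lifetime_risk_65_ref=ref.lifetime_risk_65,
    )


def restrict_to_age(result: CohortResult, cutoff: int = 85) -> CohortResult:
    """Truncate a cohort run at the cutoff birthday.

    Person-years and events at ages below ``cutoff`` are retained, so
    downstream outcomes describe the burden experienced before that age.  A
    cutoff at or beyond the table's closing age returns the run unchanged.
    """
    if cutoff > result.max_age + 1:
        raise ValueError("cutoff beyond the simulated age range")
    if cutoff >= result.max_age:
        return result
    if cutoff < 40:
        import warnings

        warnings.warn("cutoff below the onset floor age; outcomes will be trivial")
    return CohortResult(
        sex=result.sex,
        scenario=result.scenario,
        n=result.n,
        max_age=cutoff - 1,
        incidence_event=result.incidence_event,
        occupancy=result.occupancy[:cutoff].copy(),
        person_years=result.person_years[:cutoff].copy(),
        onsets_mci=result.onsets_mci[:cutoff].copy(),
        onsets_dementia=result.onsets_dementia[:cutoff].copy(),
        deaths_other=result.deaths_other[:cutoff].copy(),
        deaths_dementia=result.deaths_dementia[:cutoff].copy(),
    )


def outcome_table(
    results: dict[str, CohortResult],
    reference_label: str = "reference",
) -> pd.DataFrame:
    """Tidy table of absolute outcomes and percent changes vs reference.

    One row per scenario; the layout of the headline results table
    (adjusted rates, total cases, life years with/without dementia), with
    percent changes against the reference scenario.
    """
    if reference_label not in results:
        raise ValueError(f"missing reference scenario {reference_label!r}")
    ref_res = results[reference_label]
    ref_rep = summarize(ref_res)
    rows = []
    for label, res in results.items():
        rep = summarize(res, standard=ref_res)
        cmp = compare(ref_rep, rep)
        row = {"sex": rep.sex, "scenario": label}
        for k, v in rep.scalar_outcomes().items():
            row[k] = v
            row[f"{k}_pct_change"] = cmp.pct_change[k] if label != reference_label else 0.0
        row["crossover_age_cases"] = cmp.crossover_age_cases
        rows.append(row)
    return pd.DataFrame(rows)


def by_age_tables(
    results: dict[str, CohortResult], reference_label: str = "reference"
) -> dict[str, pd.DataFrame]:
    """By-age difference tables: cases, life years, and per-100k rates."""
    ref_res = results[reference_label]
    ref_rep = summarize(ref_res)
    ages = np.arange(ref_res.max_age + 1)
    cases, ly, per100k = [], [], []
    for label, res in results.items():
        if label == reference_label:
            continue
        cmp = compare(ref_rep, summarize(res, standard=ref_res))
        cases.append(
            pd.DataFrame(
                {"sex": cmp.sex, "scenario": label, "age": ages, "cases_diff": cmp.by_age_cases_diff}
            )
        )
        ly.append(
            pd.DataFrame(
                {
                    "sex": cmp.sex,
                    "scenario": label,
                    "age": ages,
                    "ly_with_diff": cmp.by_age_ly_with_diff,
                    "ly_without_diff": cmp.by_age_ly_without_diff,
                }
            )
        )
        per100k.append(
            pd.DataFrame(
                {
                    "sex": cmp.sex,
                    "scenario": label,
                    "age": ages,
                    "cases_per_100k_diff": cmp.per_100k_cases_diff,
                    "ly_with_per_100k_diff": cmp.per_100k_ly_with_diff,
                    "ly_without_per_100k_diff": cmp.per_100k_ly_without_diff,
                }
            )
        )
    return {
        "byage_cases": pd.concat(cases, ignore_index=True),
        "byage_ly": pd.concat(ly, ignore_index=True),
        "per100k": pd.concat(per100k, ignore_index=True),
    }
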