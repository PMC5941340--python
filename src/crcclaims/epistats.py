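"""Descriptive and comparative statistics for claims-ascertained cancer cases.

Covers the surveillance toolkit around the case-finding algorithms:

* binomial proportions with Wald 95% confidence intervals,
* pooled two-proportion z-tests (two-sided),
* relative differences between proportions,
* direct age standardization of incidence rates against a fixed reference
  population, per 100,000,
* a yearly standardized-rate series with fiscal-to-calendar truncation, and
* the case-characteristics table (sex, age band, deprivation quintile, site)
  with treatment proportions for concordant vs newly-captured cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ascertain import CandidateCase
from .codes import Site, TreatmentGroup
from .concordance import Category, ConcordanceResult
from .data import StudyPeriod, age_in_years

__all__ = [
    "ProportionEstimate",
    "ReferencePopulation",
    "proportion_ci",
    "two_prop_test",
    "relative_difference",
    "direct_standardized_rate",
    "rate_series",
    "build_table2",
    "default_reference_population",
    "AGE_BANDS_TABLE2",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

#: Age bands used in the characteristics table.
AGE_BANDS_TABLE2: tuple[tuple[str, int, int], ...] = (
    ("<50", 0, 49),
    ("50-69", 50, 69),
    ("70+", 70, 200),
)


@dataclass(frozen=True)
class ProportionEstimate:
    numerator: int
    denominator: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def percent(self) -> float:
        return 100.0 * self.p_hat


def proportion_ci(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Wald interval ``p̂ ± z·sqrt(p̂(1−p̂)/n)``, truncated to [0, 1]."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("numerator must lie in [0, n]")
    p = k / n
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(p * (1 - p) / n)
    return ProportionEstimate(k, n, p, max(0.0, p - half), min(1.0, p + half), level)


def two_prop_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test; returns (z, two-sided p-value).

    ``z²`` equals the Pearson chi-square of the 2x2 table without continuity
    correction. With a degenerate pooled proportion (0 or 1) both sample
    proportions coincide and the p-value is 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def relative_difference(p1: float, p2: float) -> float | None:
    """``100 * (p1 - p2) / p1`` — how much larger p1 is, relative to itself.

    None (NA) when p1 is zero. Inputs may be on any common scale
    (proportions or percents); the result is a percent.
    """
    if p1 == 0:
        return None
    return 100.0 * (p1 - p2) / p1


# ---------------------------------------------------------------------------
# direct standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePopulation:
    """Fixed age structure used as standardization weights.

    ``bands`` are (label, low age, high age) with inclusive bounds,
    non-overlapping and exhaustive over the cohort's age range;
    ``counts`` are the reference population in each band.
    """

    bands: tuple[tuple[str, int, int], ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.counts):
            raise ValueError("bands and counts must align")
        if any(c <= 0 for c in self.counts):
            raise ValueError("reference counts must be positive")
        for (_, lo_a, hi_a), (_, lo_b, _) in zip(self.bands, self.bands[1:]):
            if lo_b != hi_a + 1:
                raise ValueError("age bands must be contiguous and ordered")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def weights(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def band_of(self, age: int) -> str | None:
        for label, lo, hi in self.bands:
            if lo <= age <= hi:
                return label
        return None


def default_reference_population() -> ReferencePopulation:
    """Packaged stand-in reference population (synthetic age structure).

    Five-year bands from 20-24 to 85+, with counts shaped like a large
    North-American urban adult population in the mid-2000s. This is a
    synthetic stand-in: surveillance against real data should supply the
    jurisdiction's census reference table instead.
    """
    bands = [(f"{lo}-{lo + 4}", lo, lo + 4) for lo in range(20, 85, 5)] + [("85+", 85, 200)]
    counts = (490, 480, 480, 510, 600, 640, 590, 530, 430, 330, 280, 230, 170, 130)
    return ReferencePopulation(tuple(bands), tuple(float(c) * 1000 for c in counts))


def direct_standardized_rate(
    cases_by_age: Sequence[float],
    pop_by_age: Sequence[float],
    ref: ReferencePopulation,
) -> float:
    """Directly standardized rate per 100,000: ``Σ_g (cases_g/pop_g)·w_g·1e5``.

    The stratum partitions of all three arguments must agree. A stratum with
    cases but zero population is an error; an empty stratum (0/0) contributes
    a zero rate.
    """
    cases = np.asarray(cases_by_age, dtype=float)
    pop = np.asarray(pop_by_age, dtype=float)
    if cases.shape != pop.shape or cases.shape != (len(ref.bands),):
        raise ValueError("cases, populations and reference must share one age partition")
    if np.any((pop == 0) & (cases > 0)):
        raise ValueError("stratum with cases but zero population")
    rates = np.divide(cases, pop, out=np.zeros_like(cases), where=pop > 0)
    return float(np.sum(rates * ref.weights()) * 1e5)


def _year_population_by_band(
    persons: pd.DataFrame, year: int, ref: ReferencePopulation, min_age: int
) -> np.ndarray:
    """Mid-year (July 1) population of the study cohort by reference band."""
    mid = pd.Timestamp(year, 7, 1)
    alive = persons["death_date"].isna() | (persons["death_date"] >= mid)
    born = persons["birth_date"] <= mid
    sub = persons[alive & born]
    ages = sub["birth_date"].map(lambda b: age_in_years(b.date(), mid.date()))
    counts = np.zeros(len(ref.bands))
    for i, (_, lo, hi) in enumerate(ref.bands):
        lo = max(lo, min_age)
        counts[i] = int(((ages >= lo) & (ages <= hi)).sum())
    return counts


def rate_series(
    cases: Iterable[CandidateCase],
    persons: pd.DataFrame,
    ref: ReferencePopulation | None = None,
    period: StudyPeriod | None = None,
) -> pd.DataFrame:
    """Yearly crude and direct age-standardized incidence rates per 100,000.

    Cases are binned by the calendar year of their assigned diagnosis date
    and by age at diagnosis. Calendar years only partially covered by the
    (fiscal) study period are dropped — with the default April-to-March
    window this truncates the first and last fiscal years, leaving 2001-2009.
    """
    ref = ref or default_reference_population()
    period = period or StudyPeriod()
    first_full = period.start.year if period.start == date(period.start.year, 1, 1) else period.start.year + 1
    last_full = period.end.year if period.end == date(period.end.year, 12, 31) else period.end.year - 1

    birth_by_pid = persons.set_index("person_id")["birth_date"]
    binned: dict[int, np.ndarray] = {
        y: np.zeros(len(ref.bands)) for y in range(first_full, last_full + 1)
    }
    label_index = {label: i for i, label in enumerate(ref.labels)}
    for c in cases:
        y = c.diagnosis_date.year
        if y not in binned:
            continue
        age = age_in_years(birth_by_pid[c.person_id].date(), c.diagnosis_date)
        band = ref.band_of(age)
        if band is not None:
            binned[y][label_index[band]] += 1

    rows = []
    for y in sorted(binned):
        pop = _year_population_by_band(persons, y, ref, period.min_age)
        n_cases = binned[y].sum()
        n_pop = pop.sum()
        rows.append(
            {
                "year": y,
                "cases": int(n_cases),
                "population": int(n_pop),
                "crude_rate": 1e5 * n_cases / n_pop if n_pop else np.nan,
                "standardized_rate": direct_standardized_rate(binned[y], pop, ref),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# characteristics table
# ---------------------------------------------------------------------------


def _strata(persons: pd.DataFrame, case: CandidateCase) -> dict[str, str]:
    row = persons.loc[case.person_id]
    age = age_in_years(row["birth_date"].date(), case.diagnosis_date)
    band = next(label for label, lo, hi in AGE_BANDS_TABLE2 if lo <= age <= hi)
    return {
        "sex": str(row["sex"]),
        "age_band": band,
        "deprivation": f"Q{int(row['deprivation_quintile'])}",
        "site": case.site.value,
    }


def build_table2(
    cases: Iterable[CandidateCase],
    classification: Mapping[str, Category] | Iterable[ConcordanceResult],
    persons: pd.DataFrame,
) -> pd.DataFrame:
    """Characteristics of treated cases, concordant vs newly captured.

    Rows: total, sex, age bands (<50, 50-69, 70+), deprivation quintiles
    Q1-Q5, and site. For each of the two concordance groups the table gives
    the group count and its share of the group total (with Wald CI), and the
    proportions receiving surgery and chemo/radiotherapy *within that row and
    group* (with CIs). Percentages are unrounded here; rounding happens at
    write time. Empty strata yield NA cells.
    """
    if not isinstance(classification, Mapping):
        classification = {r.person_id: r.category for r in classification}
    pers = persons.set_index("person_id") if persons.index.name != "person_id" else persons

    treated = [c for c in cases if c.treatment_confirmed]
    groups: dict[str, list[CandidateCase]] = {"concordant": [], "newly_captured": []}
    for c in treated:
        cat = classification.get(c.person_id)
        if cat is Category.CONCORDANT:
            groups["concordant"].append(c)
        elif cat is Category.NEWLY_CAPTURED:
            groups["newly_captured"].append(c)

    strata = {c.person_id: _strata(pers, c) for c in treated}
    rows_def = (
        [("total", None, None)]
        + [("sex", "sex", v) for v in ("female", "male")]
        + [("age", "age_band", b[0]) for b in AGE_BANDS_TABLE2]
        + [("deprivation", "deprivation", f"Q{i}") for i in range(1, 6)]
        + [("site", "site", s.value) for s in (Site.COLON, Site.RECTUM)]
    )

    records = []
    for section, key, value in rows_def:
        rec: dict[str, object] = {
            "section": section,
            "stratum": value if value is not None else "all",
        }
        for gname, gcases in groups.items():
            sub = (
                gcases
                if key is None
                else [c for c in gcases if strata[c.person_id][key] == value]
            )
            n_group = len(gcases)
            n = len(sub)
            rec[f"{gname}_n"] = n
            if n_group:
                est = proportion_ci(n, n_group)
                rec[f"{gname}_pct"] = est.percent
                rec[f"{gname}_ci_low"] = 100 * est.ci_low
                rec[f"{gname}_ci_high"] = 100 * est.ci_high
            else:
                rec[f"{gname}_pct"] = np.nan
            for tx, label in (
                (TreatmentGroup.SURGERY, "surgery"),
                (TreatmentGroup.CHEMO_RADIO, "chemo_radio"),
            ):
                k = sum(1 for c in sub if tx in c.treatment_groups)
                col = f"{gname}_{label}"
                if n:
                    est = proportion_ci(k, n)
                    rec[f"{col}_n"] = k
                    rec[f"{col}_pct"] = est.percent
                    rec[f"{col}_ci_low"] = 100 * est.ci_low
                    rec[f"{col}_ci_high"] = 100 * est.ci_high
                else:
                    rec[f"{col}_n"] = 0
                    rec[f"{col}_pct"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)
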