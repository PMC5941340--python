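"""Registry-concordance classification and the concordance summary table.

The tumor registry is the reference point. Each algorithm's case list is
compared to the registry *by person identifier only* — no date or site
agreement is required, because registry diagnosis dates differ systematically
from claims-assigned dates. Persons fall into three categories:

* ``concordant`` — identified by both the algorithm and the registry;
* ``newly_captured`` — identified by the algorithm only;
* ``registry_only`` — in the registry but missed by the algorithm.

The summary table splits each algorithm's counts by treatment receipt and
reports the percent difference of the algorithm's *treated* total from the
registry's treated total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .ascertain import CandidateCase
from .data import round_half_up

__all__ = [
    "Category",
    "ConcordanceResult",
    "classify",
    "pct_diff",
    "untreated_rate",
    "build_table1",
]


class Category(str, Enum):
    CONCORDANT = "concordant"
    NEWLY_CAPTURED = "newly_captured"
    REGISTRY_ONLY = "registry_only"


@dataclass(frozen=True)
class ConcordanceResult:
    person_id: str
    category: Category
    treated: bool
    algorithm: str


def classify(
    cases: Iterable[CandidateCase],
    registry: pd.DataFrame,
    registry_treated: Mapping[str, bool] | None = None,
) -> list[ConcordanceResult]:
    """Partition persons into concordant / newly-captured / registry-only.

    ``registry_treated`` supplies treated status for registry-only persons
    (their events never produced a candidate); it is typically built by
    running treatment confirmation over the full dataset. Treated status for
    algorithm cases is carried from the candidate itself.
    """
    cases = list(cases)
    case_ids = [c.person_id for c in cases]
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("duplicate person among candidate cases")
    reg_ids = list(registry["person_id"])
    if len(set(reg_ids)) != len(reg_ids):
        raise ValueError("duplicate person in registry")
    registry_treated = registry_treated or {}
    algorithm = cases[0].algorithm.value if cases else "A?"

    reg_set = set(reg_ids)
    out = []
    for c in cases:
        cat = Category.CONCORDANT if c.person_id in reg_set else Category.NEWLY_CAPTURED
        out.append(ConcordanceResult(c.person_id, cat, c.treatment_confirmed, algorithm))
    seen = set(case_ids)
    for pid in reg_ids:
        if pid not in seen:
            out.append(
                ConcordanceResult(
                    pid, Category.REGISTRY_ONLY, bool(registry_treated.get(pid, False)), algorithm
                )
            )
    return sorted(out, key=lambda r: r.person_id)


def pct_diff(n_alg: int, n_registry: int) -> float | None:
    """Percent difference of an algorithm count from the registry count.

    ``100 * (n_alg - n_registry) / n_registry``, unrounded; None (NA) when
    the registry count is zero.
    """
    if n_registry == 0:
        return None
    return 100.0 * (n_alg - n_registry) / n_registry


def untreated_rate(n_untreated: int, n_total: int) -> float | None:
    """Share of identified cases with no treatment code, in percent; NA when empty."""
    if n_total == 0:
        return None
    return 100.0 * n_untreated / n_total


def _counts(results: list[ConcordanceResult]) -> dict[str, int]:
    c = {
        "untreated_concordant": 0,
        "untreated_new": 0,
        "treated_concordant": 0,
        "treated_new": 0,
    }
    for r in results:
        if r.category is Category.REGISTRY_ONLY:
            continue
        key = ("treated_" if r.treated else "untreated_") + (
            "concordant" if r.category is Category.CONCORDANT else "new"
        )
        c[key] += 1
    return c


def build_table1(
    results_by_algorithm: Mapping[str, list[ConcordanceResult]],
    registry: pd.DataFrame,
    registry_treated: Mapping[str, bool],
) -> pd.DataFrame:
    """Concordance table: registry row plus one row per algorithm.

    Columns: total; untreated and treated counts split by concordant /
    newly-captured; and the percent difference of treated totals from the
    registry's treated total (presentation-rounded to one decimal, half-up).
    """
    reg_ids = list(registry["person_id"])
    reg_treated_n = sum(bool(registry_treated.get(pid, False)) for pid in reg_ids)
    reg_untreated_n = len(reg_ids) - reg_treated_n

    rows = [
        {
            "algorithm": "registry",
            "total": len(reg_ids),
            "untreated_total": reg_untreated_n,
            "untreated_concordant": None,
            "untreated_new": None,
            "treated_total": reg_treated_n,
            "treated_concordant": None,
            "treated_new": None,
            "pct_diff": None,
        }
    ]
    for name, results in results_by_algorithm.items():
        c = _counts(results)
        untreated_total = c["untreated_concordant"] + c["untreated_new"]
        treated_total = c["treated_concordant"] + c["treated_new"]
        diff = pct_diff(treated_total, reg_treated_n)
        rows.append(
            {
                "algorithm": name,
                "total": untreated_total + treated_total,
                "untreated_total": untreated_total,
                "untreated_concordant": c["untreated_concordant"],
                "untreated_new": c["untreated_new"],
                "treated_total": treated_total,
                "treated_concordant": c["treated_concordant"],
                "treated_new": c["treated_new"],
                "pct_diff": None if diff is None else round_half_up(diff, 1),
            }
        )
    return pd.DataFrame(rows)
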