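"""Incident colorectal-cancer case-finding over linked claims data.

Three algorithms, differing in source data:

* **A1 (inpatient)** — any hospital admission carrying at least one CRC
  diagnostic code, in any diagnostic position. Diagnosis date = admission
  date of the earliest qualifying admission.
* **A2 (outpatient two-claim rule)** — two CRC-coded physician billing
  claims on distinct dates separated by at least ``min_separation_days``
  (default 30) within ``max_window_days`` (default 730, i.e. two years,
  inclusive bounds). Diagnosis date = the earliest first-of-pair date. The
  separation requirement screens out isolated "rule-out" codes recorded
  while a cancer work-up is still in progress.
* **A3 (union)** — a person qualifying under A1 and/or A2; diagnosis date is
  whichever comes first.

Treatment confirmation looks for any CRC-directed treatment code (surgical,
chemo/radiotherapy, or other) in billing acts or hospital intervention codes
anywhere in the study period, before or after the assigned diagnosis date.
Requiring treatment raises positive predictive value at the cost of dropping
genuinely untreated cases.

One incident case per person: the first qualifying event wins, and no
recurrence detection is attempted. Site ties on the earliest evidence
(both colon and rectum codes present) resolve to colon and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum

import pandas as pd

from .codes import CodeSet, ICDVersion, Site, TreatmentGroup, normalize_code
from .data import LinkedDataset, split_codes

__all__ = [
    "Algorithm",
    "WindowRule",
    "CandidateCase",
    "find_hospital_case",
    "find_billing_case",
    "combine_union",
    "confirm_treatment",
    "treatment_by_person",
    "run_ascertainment",
    "cases_to_frame",
]

log = logging.getLogger(__name__)

_SITE_PRIORITY = {Site.COLON: 0, Site.RECTUM: 1, Site.UNSPECIFIED: 2}


class Algorithm(str, Enum):
    A1 = "A1"  # hospitalization diagnosis
    A2 = "A2"  # billing two-claim temporal rule
    A3 = "A3"  # union of A1 and A2


@dataclass(frozen=True)
class WindowRule:
    """Temporal constraints of the outpatient two-claim rule (inclusive bounds)."""

    min_separation_days: int = 30
    max_window_days: int = 730

    def __post_init__(self) -> None:
        if not (0 < self.min_separation_days <= self.max_window_days):
            raise ValueError("require 0 < min_separation_days <= max_window_days")


@dataclass(frozen=True)
class CandidateCase:
    """A person flagged incident by one algorithm, with its evidence trail."""

    person_id: str
    algorithm: Algorithm
    diagnosis_date: date
    site: Site
    evidence: tuple[tuple[str, date, str], ...]  # (source, event date, code)
    treatment_confirmed: bool = False
    treatment_groups: frozenset[TreatmentGroup] = field(default_factory=frozenset)


def _pick_site(codes_with_versions: list[tuple[str, str]], cs: CodeSet, person_id: str) -> Site:
    """Site from a set of same-date matching codes; colon wins ties, logged."""
    sites = {cs.site_of(c, v) for c, v in codes_with_versions}
    sites.discard(Site.UNSPECIFIED)
    if not sites:
        return Site.UNSPECIFIED
    if len(sites) > 1:
        log.info("person %s: colon and rectum codes on the same earliest evidence; colon assigned", person_id)
    return min(sites, key=_SITE_PRIORITY.__getitem__)


def find_hospital_case(admissions: pd.DataFrame, cs: CodeSet) -> CandidateCase | None:
    """Inpatient rule (A1) for one person's admissions; None when nothing matches."""
    best: tuple[date, list[tuple[str, str]]] | None = None
    for row in admissions.itertuples(index=False):
        codes = split_codes(row.dx_codes)
        versions = split_codes(row.dx_versions)
        matches = [
            (c, v)
            for c, v in zip(codes, versions)
            if cs.match_dx(c, v)
        ]
        if not matches:
            continue
        adm = row.admission_date.date() if hasattr(row.admission_date, "date") else row.admission_date
        if best is None or adm < best[0]:
            best = (adm, matches)
    if best is None:
        return None
    adm_date, matches = best
    person_id = str(admissions["person_id"].iloc[0])
    return CandidateCase(
        person_id=person_id,
        algorithm=Algorithm.A1,
        diagnosis_date=adm_date,
        site=_pick_site(matches, cs, person_id),
        evidence=tuple(sorted(("admission", adm_date, normalize_code(c)) for c, _ in matches)),
    )


def find_billing_case(
    claims: pd.DataFrame, cs: CodeSet, rule: WindowRule = WindowRule()
) -> CandidateCase | None:
    """Outpatient two-claim rule (A2) for one person's billing claims.

    Duplicate same-date claims collapse to one date and can never satisfy the
    separation requirement on their own. The assigned diagnosis date is the
    smallest date that participates in any qualifying pair.
    """
    crc = claims[
        claims["dx_code"].notna()
        & claims.apply(lambda r: bool(r["dx_code"]) and cs.match_dx(r["dx_code"], r["dx_version"]), axis=1)
    ]
    if crc.empty:
        return None
    dates = sorted({d.date() if hasattr(d, "date") else d for d in crc["service_date"]})
    lo, hi = rule.min_separation_days, rule.max_window_days
    first: date | None = None
    for i, d1 in enumerate(dates):
        if any(lo <= (d2 - d1).days <= hi for d2 in dates[i + 1 :]):
            first = d1
            break
    if first is None:
        return None
    svc = crc["service_date"].map(lambda d: d.date() if hasattr(d, "date") else d)
    on_first = crc[svc == first]
    matches = [(r.dx_code, r.dx_version) for r in on_first.itertuples(index=False)]
    person_id = str(claims["person_id"].iloc[0])
    return CandidateCase(
        person_id=person_id,
        algorithm=Algorithm.A2,
        diagnosis_date=first,
        site=_pick_site(matches, cs, person_id),
        evidence=tuple(sorted(("billing", first, normalize_code(c)) for c, _ in matches)),
    )


def combine_union(
    c1: CandidateCase | None, c2: CandidateCase | None
) -> CandidateCase | None:
    """Union rule (A3): earliest of the available dates, evidence merged."""
    if c1 is None and c2 is None:
        return None
    if c1 is not None and c2 is not None and c1.person_id != c2.person_id:
        raise ValueError(f"cannot union cases of different persons: {c1.person_id} vs {c2.person_id}")
    if c1 is None or (c2 is not None and c2.diagnosis_date < c1.diagnosis_date):
        earlier, other = c2, c1
    else:
        earlier, other = c1, c2
    assert earlier is not None
    evidence = earlier.evidence + (other.evidence if other is not None else ())
    return replace(earlier, algorithm=Algorithm.A3, evidence=evidence)


def confirm_treatment(
    billing: pd.DataFrame, admissions: pd.DataFrame, cs: CodeSet
) -> tuple[bool, frozenset[TreatmentGroup]]:
    """Any CRC treatment code anywhere in the (already period-filtered) events.

    Scans billing act codes and hospital intervention codes; returns the
    matched therapeutic groups.
    """
    groups: set[TreatmentGroup] = set()
    for act in billing["act_code"]:
        if act:
            g = cs.match_treatment(act)
            if g is not None:
                groups.add(g)
    for cell in admissions["intervention_codes"]:
        for code in split_codes(cell):
            g = cs.match_treatment(code)
            if g is not None:
                groups.add(g)
    return bool(groups), frozenset(groups)


def treatment_by_person(dataset: LinkedDataset, cs: CodeSet) -> dict[str, frozenset[TreatmentGroup]]:
    """Vectorized person -> matched treatment groups over the whole dataset."""
    by_person: dict[str, set[TreatmentGroup]] = {}
    acts = dataset.billing[dataset.billing["act_code"].notna()][["person_id", "act_code"]]
    if len(acts):
        norm = acts["act_code"].map(normalize_code)
        for group, codes in cs.treatment_codes.items():
            hit = acts.loc[norm.isin(codes), "person_id"]
            for pid in hit:
                by_person.setdefault(pid, set()).add(group)
    adm = dataset.admissions[dataset.admissions["intervention_codes"].notna()]
    for row in adm.itertuples(index=False):
        for code in split_codes(row.intervention_codes):
            g = cs.match_treatment(code)
            if g is not None:
                by_person.setdefault(row.person_id, set()).add(g)
    return {pid: frozenset(gs) for pid, gs in by_person.items()}


def _crc_billing_mask(billing: pd.DataFrame, cs: CodeSet) -> pd.Series:
    norm = billing["dx_code"].fillna("").map(normalize_code)
    mask = pd.Series(False, index=billing.index)
    for version, prefixes in (
        (ICDVersion.ICD9.value, cs.icd9_prefixes),
        (ICDVersion.ICD10.value, cs.icd10_prefixes),
    ):
        vmask = billing["dx_version"] == version
        for p in prefixes:
            mask |= vmask & norm.str.startswith(normalize_code(p))
    return mask


def _admission_has_crc(admissions: pd.DataFrame, cs: CodeSet) -> pd.Series:
    def _hit(row) -> bool:
        return any(
            cs.match_dx(c, v)
            for c, v in zip(split_codes(row.dx_codes), split_codes(row.dx_versions))
        )

    if admissions.empty:
        return pd.Series(False, index=admissions.index)
    return pd.Series([_hit(r) for r in admissions.itertuples(index=False)], index=admissions.index)


def run_ascertainment(
    dataset: LinkedDataset,
    algorithm: Algorithm | str,
    cs: CodeSet | None = None,
    rule: WindowRule = WindowRule(),
    lookback_days: int | None = None,
) -> list[CandidateCase]:
    """Run one algorithm over a validated dataset.

    Returns at most one :class:`CandidateCase` per person, sorted by
    ``person_id``, each with ``treatment_confirmed`` populated. Output is
    invariant to input row order.

    ``lookback_days``, when set, drops cases whose assigned diagnosis date
    falls within that many days of the period start — an optional prevalence
    washout, off by default.
    """
    from .codes import default_code_set

    algorithm = Algorithm(algorithm)
    cs = cs or default_code_set()

    hosp_cases: dict[str, CandidateCase] = {}
    if algorithm in (Algorithm.A1, Algorithm.A3):
        flagged = dataset.admissions[_admission_has_crc(dataset.admissions, cs)]
        for pid, grp in flagged.groupby("person_id", sort=False):
            case = find_hospital_case(grp, cs)
            if case is not None:
                hosp_cases[pid] = case

    bill_cases: dict[str, CandidateCase] = {}
    if algorithm in (Algorithm.A2, Algorithm.A3):
        crc_claims = dataset.billing[_crc_billing_mask(dataset.billing, cs)]
        for pid, grp in crc_claims.groupby("person_id", sort=False):
            case = find_billing_case(grp, cs, rule)
            if case is not None:
                bill_cases[pid] = case

    if algorithm is Algorithm.A1:
        merged = hosp_cases
    elif algorithm is Algorithm.A2:
        merged = bill_cases
    else:
        merged = {
            pid: combine_union(hosp_cases.get(pid), bill_cases.get(pid))
            for pid in set(hosp_cases) | set(bill_cases)
        }

    if lookback_days is not None:
        cutoff = dataset.period.start + timedelta(days=lookback_days)
        merged = {pid: c for pid, c in merged.items() if c.diagnosis_date >= cutoff}

    treated = treatment_by_person(dataset, cs)
    out = []
    for pid in sorted(merged):
        case = merged[pid]
        groups = treated.get(pid, frozenset())
        out.append(replace(case, treatment_confirmed=bool(groups), treatment_groups=groups))
    return out


def cases_to_frame(cases: list[CandidateCase]) -> pd.DataFrame:
    """Tabular view of cases (the ``cases.csv`` layout)."""
    return pd.DataFrame(
        {
            "person_id": [c.person_id for c in cases],
            "algorithm": [c.algorithm.value for c in cases],
            "diagnosis_date": [c.diagnosis_date.isoformat() for c in cases],
            "site": [c.site.value for c in cases],
            "treatment_confirmed": [c.treatment_confirmed for c in cases],
            "treatment_groups": [
                "|".join(sorted(g.value for g in c.treatment_groups)) for c in cases
            ],
            "evidence_n": [len(c.evidence) for c in cases],
        }
    )
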