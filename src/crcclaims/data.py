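"""Domain types and readers/writers for the four linked administrative tables.

The linkage structure mirrors a provincial single-payer claims environment:
every table is keyed by an anonymized person identifier, and four tables are
linked — person demographics, physician fee-for-service billing claims,
hospital admissions, and tumor-registry cases.

File conventions (all CSV, UTF-8, header row, ISO-8601 dates):

``persons.csv``
    person_id, birth_date, sex {female|male}, deprivation_quintile {1..5},
    death_date (may be empty)
``billing.csv``
    person_id, service_date, dx_code, dx_version {ICD9|ICD10}, act_code
    (dx_code and act_code may each be empty, not both)
``admissions.csv``
    person_id, admission_date, discharge_date, dx_codes, dx_versions,
    intervention_codes — the three code columns are ``|``-delimited lists so
    one row preserves one admission with all its diagnostic positions
``registry.csv``
    person_id, diagnosis_date, site {colon|rectum|unspecified}
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import ICDVersion, Site

__all__ = [
    "StudyPeriod",
    "LinkedDataset",
    "SchemaError",
    "RowParseError",
    "LinkageError",
    "read_dataset",
    "write_report",
    "age_in_years",
]

log = logging.getLogger(__name__)

LIST_SEP = "|"

_SCHEMAS = {
    "persons": ["person_id", "birth_date", "sex", "deprivation_quintile", "death_date"],
    "billing": ["person_id", "service_date", "dx_code", "dx_version", "act_code"],
    "admissions": [
        "person_id",
        "admission_date",
        "discharge_date",
        "dx_codes",
        "dx_versions",
        "intervention_codes",
    ],
    "registry": ["person_id", "diagnosis_date", "site"],
}

_DATE_COLS = {
    "persons": ["birth_date", "death_date"],
    "billing": ["service_date"],
    "admissions": ["admission_date", "discharge_date"],
    "registry": ["diagnosis_date"],
}


class SchemaError(ValueError):
    """A required column is missing or has an invalid domain."""


class RowParseError(ValueError):
    """A row-level value (typically a date) could not be parsed."""


class LinkageError(ValueError):
    """An event table references a person absent from the persons table."""


@dataclass(frozen=True)
class StudyPeriod:
    """Observation window and minimum cohort age.

    Defaults follow a ten-fiscal-year surveillance window (April 2000 through
    March 2010) over the population aged 20 and older.
    """

    start: date = date(2000, 4, 1)
    end: date = date(2010, 3, 31)
    min_age: int = 20

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("study period end must be after start")
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


def age_in_years(birth: date, at: date) -> int:
    """Age in completed years at a given date."""
    return at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))


@dataclass
class LinkedDataset:
    """Validated, period-filtered in-memory view of the four linked tables."""

    persons: pd.DataFrame
    billing: pd.DataFrame
    admissions: pd.DataFrame
    registry: pd.DataFrame
    period: StudyPeriod = field(default_factory=StudyPeriod)
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pids = set(self.persons["person_id"])
        if len(pids) != len(self.persons):
            dup = self.persons["person_id"][self.persons["person_id"].duplicated()]
            raise SchemaError(f"duplicate person_id in persons table: {sorted(set(dup))[:5]}")
        for name in ("billing", "admissions", "registry"):
            tab = getattr(self, name)
            unknown = set(tab["person_id"]) - pids
            if unknown:
                raise LinkageError(
                    f"{name} references {len(unknown)} unknown person_id(s): "
                    f"{sorted(unknown)[:5]}"
                )
        if self.registry["person_id"].duplicated().any():
            raise SchemaError("registry holds more than one case for some person (incidence only)")


def _parse_dates(df: pd.DataFrame, table: str, cols: list[str]) -> pd.DataFrame:
    for col in cols:
        raw = df[col].astype("string").str.strip()
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
            raise RowParseError(
                f"{table}.{col}: unparseable date {raw[bad].iloc[0]!r} at line {line}"
            )
        df[col] = parsed
    return df


def _read_table(path: str | Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} ({path}): missing column(s) {missing}")
    df = df.replace({"": None})
    return _parse_dates(df, table, _DATE_COLS[table])


def read_dataset(
    persons_path: str | Path,
    billing_path: str | Path,
    admissions_path: str | Path,
    registry_path: str | Path,
    period: StudyPeriod | None = None,
) -> LinkedDataset:
    """Read, validate, link, and period/age-filter the four tables.

    Events dated outside the study period, or occurring before the person
    reached ``period.min_age``, are excluded and counted in
    ``LinkedDataset.exclusions``. Events after a person's recorded death date
    are rejected with a warning. Filtering is idempotent.
    """
    period = period or StudyPeriod()
    persons = _read_table(persons_path, "persons")
    if persons["birth_date"].isna().any():
        raise SchemaError("persons: birth_date required for every person")
    q = pd.to_numeric(persons["deprivation_quintile"], errors="coerce")
    if q.isna().any() or not q.isin([1, 2, 3, 4, 5]).all():
        raise SchemaError("persons: deprivation_quintile must be an integer in 1..5")
    persons["deprivation_quintile"] = q.astype(int)
    bad_sex = ~persons["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise SchemaError(f"persons: sex must be female|male, got {persons['sex'][bad_sex].iloc[0]!r}")
    dead_before_born = persons["death_date"].notna() & (persons["death_date"] < persons["birth_date"])
    if dead_before_born.any():
        raise SchemaError("persons: death_date precedes birth_date")

    billing = _read_table(billing_path, "billing")
    if ((billing["dx_code"].isna()) & (billing["act_code"].isna())).any():
        raise SchemaError("billing: rows must carry a dx_code or an act_code")
    bad_ver = billing["dx_code"].notna() & ~billing["dx_version"].isin([v.value for v in ICDVersion])
    if bad_ver.any():
        raise SchemaError("billing: dx_version must be ICD9|ICD10 when dx_code present")

    admissions = _read_table(admissions_path, "admissions")
    if (admissions["discharge_date"] < admissions["admission_date"]).any():
        raise SchemaError("admissions: discharge before admission")

    registry = _read_table(registry_path, "registry")
    bad_site = ~registry["site"].isin([s.value for s in Site])
    if bad_site.any():
        raise SchemaError(f"registry: unknown site {registry['site'][bad_site].iloc[0]!r}")

    pids = set(persons["person_id"])
    for name, tab in (("billing", billing), ("admissions", admissions), ("registry", registry)):
        unknown = set(tab["person_id"]) - pids
        if unknown:
            raise LinkageError(
                f"{name} references {len(unknown)} unknown person_id(s): {sorted(unknown)[:5]}"
            )

    exclusions: dict[str, int] = {}
    ref = persons.set_index("person_id")[["birth_date", "death_date"]]

    def _filter_events(df: pd.DataFrame, table: str, date_col: str) -> pd.DataFrame:
        n0 = len(df)
        dates = df[date_col]
        in_period = dates.dt.date.map(period.contains).fillna(False)
        birth = df["person_id"].map(ref["birth_date"])
        death = df["person_id"].map(ref["death_date"])
        # completed-years age at event
        years = dates.dt.year - birth.dt.year
        before_bday = (
            (dates.dt.month < birth.dt.month)
            | ((dates.dt.month == birth.dt.month) & (dates.dt.day < birth.dt.day))
        )
        age = years - before_bday.astype(int)
        of_age = age >= period.min_age
        post_death = death.notna() & (dates > death)
        if post_death.any():
            log.warning(
                "%s: rejected %d event(s) dated after the person's death", table, int(post_death.sum())
            )
        keep = in_period & of_age & ~post_death & (dates >= birth)
        out = df[keep].reset_index(drop=True)
        exclusions[table] = n0 - len(out)
        log.info("%s: %d rows read, %d kept after period/age filter", table, n0, len(out))
        return out

    billing = _filter_events(billing, "billing", "service_date")
    admissions = _filter_events(admissions, "admissions", "admission_date")
    registry = _filter_events(registry, "registry", "diagnosis_date")

    return LinkedDataset(
        persons=persons,
        billing=billing,
        admissions=admissions,
        registry=registry,
        period=period,
        exclusions=exclusions,
    )


def split_codes(value: str | None) -> list[str]:
    """Split a ``|``-delimited code-list cell; empty cell -> empty list."""
    if value is None or value == "":
        return []
    return [v for v in str(value).split(LIST_SEP) if v]


def write_report(table: pd.DataFrame, path: str | Path, decimals: int = 1) -> None:
    """Write a report table as CSV, rounding float columns half-up to ``decimals``.

    Rounding is presentation-only; callers keep unrounded values in memory.
    A round-trip read reproduces the written values.
    """
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda x: np.nan if pd.isna(x) else float(round_half_up(x, decimals))
            )
    out.to_csv(path, index=False)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), unlike banker's rounding."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
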