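"""Shared builders for small hand-written linked datasets."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from crcclaims import LinkedDataset, StudyPeriod, default_code_set


def persons_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "birth_date": "1950-06-15",
        "sex": "female",
        "deprivation_quintile": 3,
        "death_date": None,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    for c in ("birth_date", "death_date"):
        out[c] = pd.to_datetime(out[c])
    return out


def billing_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["person_id", "service_date", "dx_code", "dx_version", "act_code"]
    defaults = {"dx_code": None, "dx_version": None, "act_code": None}
    out = pd.DataFrame([{**defaults, **r} for r in rows], columns=cols)
    out["service_date"] = pd.to_datetime(out["service_date"])
    return out


def admissions_frame(rows: list[dict]) -> pd.DataFrame:
    cols = [
        "person_id",
        "admission_date",
        "discharge_date",
        "dx_codes",
        "dx_versions",
        "intervention_codes",
    ]
    defaults = {"dx_codes": None, "dx_versions": None, "intervention_codes": None}
    out = pd.DataFrame([{**defaults, **r} for r in rows], columns=cols)
    for c in ("admission_date", "discharge_date"):
        out[c] = pd.to_datetime(out[c])
    return out


def registry_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["person_id", "diagnosis_date", "site"]
    defaults = {"site": "colon"}
    out = pd.DataFrame([{**defaults, **r} for r in rows], columns=cols)
    out["diagnosis_date"] = pd.to_datetime(out["diagnosis_date"])
    return out


def make_dataset(
    persons: list[dict],
    billing: list[dict] = (),
    admissions: list[dict] = (),
    registry: list[dict] = (),
    period: StudyPeriod | None = None,
) -> LinkedDataset:
    """Assemble a validated LinkedDataset from terse row dicts."""
    return LinkedDataset(
        persons=persons_frame(persons),
        billing=billing_frame(list(billing)),
        admissions=admissions_frame(list(admissions)),
        registry=registry_frame(list(registry)),
        period=period or StudyPeriod(),
    )


@pytest.fixture(scope="session")
def codeset():
    return default_code_set()


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort shared by read-only tests."""
    from crcclaims import SimulationConfig, simulate

    config = SimulationConfig(n_persons=20_000)
    dataset, truth = simulate(config, seed=7)
    return config, dataset, truth
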