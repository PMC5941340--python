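"""Case-finding algorithms: inpatient rule, two-claim rule, union, treatment."""

import random
from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crcclaims import (
    Algorithm,
    Site,
    TreatmentGroup,
    WindowRule,
    combine_union,
    confirm_treatment,
    find_billing_case,
    find_hospital_case,
    run_ascertainment,
)
from tests.conftest import admissions_frame, billing_frame, make_dataset

D0 = date(2003, 1, 1)


def _claims(pid: str, days: list[int], code: str = "153.9", version: str = "ICD9"):
    return billing_frame(
        [
            {"person_id": pid, "service_date": (D0 + timedelta(days=d)).isoformat(),
             "dx_code": code, "dx_version": version}
            for d in days
        ]
    )


# --- inpatient rule --------------------------------------------------------


def test_single_qualifying_admission(codeset):
    adm = admissions_frame(
        [{"person_id": "p1", "admission_date": "2003-05-02", "discharge_date": "2003-05-09",
          "dx_codes": "I10|C18.2", "dx_versions": "ICD10|ICD10"}]
    )
    case = find_hospital_case(adm, codeset)
    assert case.diagnosis_date == date(2003, 5, 2)
    assert case.site is Site.COLON


def test_no_crc_codes_yields_none(codeset):
    adm = admissions_frame(
        [{"person_id": "p1", "admission_date": "2003-05-02", "discharge_date": "2003-05-09",
          "dx_codes": "I10|K52.9", "dx_versions": "ICD10|ICD10"}]
    )
    assert find_hospital_case(adm, codeset) is None


def test_earliest_qualifying_admission_wins(codeset):
    adm = admissions_frame(
        [
            {"person_id": "p1", "admission_date": "2004-02-01", "discharge_date": "2004-02-08",
             "dx_codes": "C18.9", "dx_versions": "ICD10"},
            {"person_id": "p1", "admission_date": "2002-07-09", "discharge_date": "2002-07-16",
             "dx_codes": "C20", "dx_versions": "ICD10"},
        ]
    )
    case = find_hospital_case(adm, codeset)
    assert case.diagnosis_date == date(2002, 7, 9)
    assert case.site is Site.RECTUM  # from the admission supplying the date


def test_site_tie_on_same_admission_resolves_to_colon(codeset):
    adm = admissions_frame(
        [{"person_id": "p1", "admission_date": "2003-05-02", "discharge_date": "2003-05-09",
          "dx_codes": "C20|C18.2", "dx_versions": "ICD10|ICD10"}]
    )
    assert find_hospital_case(adm, codeset).site is Site.COLON


# --- outpatient two-claim rule ---------------------------------------------


@pytest.mark.parametrize(
    "days,expected_day",
    [
        ([0, 30], 0),  # 30-day separation is inclusive
        ([0, 29], None),  # below the separation floor
        ([0, 10, 45], 0),  # the 0-45 pair qualifies, dated at its first claim
        ([0, 731], None),  # outside the 730-day window
        ([0, 730], 0),  # window bound is inclusive
        ([0], None),
        ([0, 0], None),  # same-date duplicates collapse to one date
        ([100, 40, 0, 20], 0),  # order-free; 0-40 qualifies
        ([0, 20, 900, 940], 900),  # early claims never pair; later pair wins
    ],
)
def test_two_claim_rule(codeset, days, expected_day):
    case = find_billing_case(_claims("p1", days), codeset)
    if expected_day is None:
        assert case is None
    else:
        assert case.diagnosis_date == D0 + timedelta(days=expected_day)


def test_two_claim_rule_ignores_non_crc_claims(codeset):
    claims = pd.concat(
        [_claims("p1", [0]), _claims("p1", [40], code="401.9")], ignore_index=True
    )
    assert find_billing_case(claims, codeset) is None


def test_custom_window_rule(codeset):
    rule = WindowRule(min_separation_days=60, max_window_days=90)
    assert find_billing_case(_claims("p1", [0, 59]), codeset, rule) is None
    assert find_billing_case(_claims("p1", [0, 60]), codeset, rule) is not None
    assert find_billing_case(_claims("p1", [0, 91]), codeset, rule) is None


def _oracle_first_pair_day(days: list[int], lo: int = 30, hi: int = 730):
    """Exhaustive all-pairs reference for the two-claim rule."""
    dates = sorted(set(days))
    qualifying = [
        d1 for d1 in dates for d2 in dates if d1 < d2 and lo <= d2 - d1 <= hi
    ]
    return min(qualifying) if qualifying else None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1200), min_size=1, max_size=20))
def test_two_claim_rule_matches_allpairs_oracle(days):
    codeset = __import__("crcclaims").default_code_set()
    case = find_billing_case(_claims("p1", days), codeset)
    expected = _oracle_first_pair_day(days)
    if expected is None:
        assert case is None
    else:
        assert case.diagnosis_date == D0 + timedelta(days=expected)


# --- union and treatment ---------------------------------------------------


def test_union_takes_earliest_date(codeset):
    hosp = find_hospital_case(
        admissions_frame(
            [{"person_id": "p1", "admission_date": "2004-03-01", "discharge_date": "2004-03-08",
              "dx_codes": "C18.9", "dx_versions": "ICD10"}]
        ),
        codeset,
    )
    bill = find_billing_case(
        billing_frame(
            [{"person_id": "p1", "service_date": "2003-11-15", "dx_code": "154.1", "dx_version": "ICD9"},
             {"person_id": "p1", "service_date": "2004-01-05", "dx_code": "154.1", "dx_version": "ICD9"}]
        ),
        codeset,
    )
    combined = combine_union(hosp, bill)
    assert combined.diagnosis_date == date(2003, 11, 15)
    assert combined.site is Site.RECTUM  # from the evidence supplying the date
    assert combined.algorithm is Algorithm.A3


def test_union_identity_and_empty(codeset):
    hosp = find_hospital_case(
        admissions_frame(
            [{"person_id": "p1", "admission_date": "2004-03-01", "discharge_date": "2004-03-08",
              "dx_codes": "C18.9", "dx_versions": "ICD10"}]
        ),
        codeset,
    )
    only = combine_union(hosp, None)
    assert only.diagnosis_date == hosp.diagnosis_date
    assert combine_union(None, None) is None


def test_union_rejects_mixed_persons(codeset):
    a = find_hospital_case(
        admissions_frame(
            [{"person_id": "p1", "admission_date": "2004-03-01", "discharge_date": "2004-03-02",
              "dx_codes": "C18.9", "dx_versions": "ICD10"}]
        ),
        codeset,
    )
    b = find_hospital_case(
        admissions_frame(
            [{"person_id": "p2", "admission_date": "2004-03-01", "discharge_date": "2004-03-02",
              "dx_codes": "C18.9", "dx_versions": "ICD10"}]
        ),
        codeset,
    )
    with pytest.raises(ValueError):
        combine_union(a, b)


def test_confirm_treatment_any_time_in_period(codeset):
    billing = billing_frame(
        [{"person_id": "p1", "service_date": "2002-01-01", "act_code": "CHEMO-FOLFOX"}]
    )
    admissions = admissions_frame([])
    ok, groups = confirm_treatment(billing, admissions, codeset)
    assert ok and groups == {TreatmentGroup.CHEMO_RADIO}

    none_ok, none_groups = confirm_treatment(billing_frame([]), admissions, codeset)
    assert not none_ok and none_groups == frozenset()


def test_confirm_treatment_reads_hospital_interventions(codeset):
    admissions = admissions_frame(
        [{"person_id": "p1", "admission_date": "2003-05-02", "discharge_date": "2003-05-09",
          "intervention_codes": "SURG-LAR"}]
    )
    ok, groups = confirm_treatment(billing_frame([]), admissions, codeset)
    assert ok and groups == {TreatmentGroup.SURGERY}


# --- whole-dataset runs ----------------------------------------------------


def _random_dataset(seed: int, n_persons: int = 25):
    rng = random.Random(seed)
    persons = [{"person_id": f"p{i}"} for i in range(n_persons)]
    billing, admissions = [], []
    for i in range(n_persons):
        for _ in range(rng.randint(0, 4)):
            billing.append(
                {
                    "person_id": f"p{i}",
                    "service_date": (D0 + timedelta(days=rng.randint(0, 2000))).isoformat(),
                    "dx_code": rng.choice(["153.9", "154.1", "401.9"]),
                    "dx_version": "ICD9",
                }
            )
        if rng.random() < 0.3:
            d = D0 + timedelta(days=rng.randint(0, 2000))
            admissions.append(
                {
                    "person_id": f"p{i}",
                    "admission_date": d.isoformat(),
                    "discharge_date": (d + timedelta(days=5)).isoformat(),
                    "dx_codes": rng.choice(["C18.9", "I10"]),
                    "dx_versions": "ICD10",
                }
            )
        if rng.random() < 0.4:
            billing.append(
                {
                    "person_id": f"p{i}",
                    "service_date": (D0 + timedelta(days=rng.randint(0, 2000))).isoformat(),
                    "act_code": rng.choice(["SURG-COLECT", "CHEMO-FU"]),
                }
            )
    return make_dataset(persons, billing, admissions)


@pytest.mark.parametrize("seed", range(8))
def test_union_algorithm_equals_set_union(codeset, seed):
    ds = _random_dataset(seed)
    a1 = {c.person_id: c for c in run_ascertainment(ds, "A1", codeset)}
    a2 = {c.person_id: c for c in run_ascertainment(ds, "A2", codeset)}
    a3 = {c.person_id: c for c in run_ascertainment(ds, "A3", codeset)}
    assert set(a3) == set(a1) | set(a2)
    assert len(a3) >= max(len(a1), len(a2))
    for pid in set(a1) & set(a2):
        assert a3[pid].diagnosis_date == min(a1[pid].diagnosis_date, a2[pid].diagnosis_date)


@pytest.mark.parametrize("seed", range(4))
def test_output_invariant_to_row_order(codeset, seed):
    import dataclasses

    ds = _random_dataset(seed)
    shuffled = dataclasses.replace(
        ds,
        billing=ds.billing.sample(frac=1, random_state=99).reset_index(drop=True),
        admissions=ds.admissions.sample(frac=1, random_state=99).reset_index(drop=True),
    )
    for alg in ("A1", "A2", "A3"):
        assert run_ascertainment(ds, alg, codeset) == run_ascertainment(shuffled, alg, codeset)


@pytest.mark.parametrize("seed", range(4))
def test_treatment_confirmation_is_monotone_filter(codeset, seed):
    ds = _random_dataset(seed)
    for alg in ("A1", "A2", "A3"):
        cases = run_ascertainment(ds, alg, codeset)
        confirmed = [c for c in cases if c.treatment_confirmed]
        assert len(confirmed) <= len(cases)


def test_one_case_per_person_sorted(codeset):
    ds = _random_dataset(3)
    cases = run_ascertainment(ds, "A3", codeset)
    ids = [c.person_id for c in cases]
    assert ids == sorted(ids)
    assert len(ids) == len(set(ids))


def test_lookback_washout_drops_early_cases(codeset):
    adm = [
        {"person_id": "p0", "admission_date": "2000-05-01", "discharge_date": "2000-05-08",
         "dx_codes": "C18.9", "dx_versions": "ICD10"},
        {"person_id": "p1", "admission_date": "2005-05-01", "discharge_date": "2005-05-08",
         "dx_codes": "C18.9", "dx_versions": "ICD10"},
    ]
    ds = make_dataset([{"person_id": "p0"}, {"person_id": "p1"}], [], adm)
    assert len(run_ascertainment(ds, "A1", codeset)) == 2
    washed = run_ascertainment(ds, "A1", codeset, lookback_days=365)
    assert [c.person_id for c in washed] == ["p1"]
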