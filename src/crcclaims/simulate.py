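"""Seeded generator of linked synthetic administrative health datasets.

The generator emulates the linkage structure of a single-payer claims
environment: a person demographics table, physician fee-for-service billing
claims, hospital admissions, and a tumor registry, all keyed by an anonymized
person identifier, with known ground truth for every person.

The statistical structure encodes the mechanism that motivates claims-based
case ascertainment: the registry captures cases *principally through
hospitalization*, so its capture probability is high for hospitalized cases
and low for cases managed entirely in outpatient settings. Younger and more
socioeconomically privileged cases are modestly less likely to be captured,
producing the differential-undercount pattern a claims algorithm is built to
expose. False-positive pressure comes from "rule-out" diagnostic codes:
non-cases occasionally emit CRC-coded billing claims during a work-up,
mostly as isolated single claims that the two-claim temporal rule correctly
ignores, rarely as a qualifying pair.

All randomness flows from a single seed through named substreams, so adding
a parameter never perturbs unrelated draws, and a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .ascertain import CandidateCase
from .codes import Site
from .data import LinkedDataset, StudyPeriod

__all__ = ["SimulationConfig", "simulate", "summarize_truth", "write_dataset_csv"]

_DAY = np.timedelta64(1, "D")

#: 5-year age bands 20-24 … 85+ used for the cohort age mix and incidence.
AGE_BANDS = tuple((lo, lo + 4) for lo in range(20, 85, 5)) + ((85, 109),)

#: Cohort age mix (urban adult population, mid-2000s shape), sums to 1.
DEFAULT_AGE_MIX = (
    np.array([490, 480, 480, 510, 600, 640, 590, 530, 430, 330, 280, 230, 170, 130], float)
)
DEFAULT_AGE_MIX = tuple(DEFAULT_AGE_MIX / DEFAULT_AGE_MIX.sum())

#: Annual CRC incidence per 100,000 by age band — steeply age-graded, as in
#: North-American surveillance for the 2000s.
DEFAULT_INCIDENCE = (1.5, 2.5, 4, 7, 13, 25, 50, 85, 130, 190, 250, 300, 340, 350)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    n_persons: int = 200_000
    period: StudyPeriod = field(default_factory=StudyPeriod)
    age_mix: tuple[float, ...] = DEFAULT_AGE_MIX
    female_share: float = 0.51
    quintile_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    incidence_per_1e5: tuple[float, ...] = DEFAULT_INCIDENCE
    colon_share: float = 0.67
    p_hospitalized: float = 0.80
    p_capture_hospitalized: float = 0.98
    p_capture_outpatient: float = 0.05
    capture_mult_under50: float = 0.90  # registry undercounts younger cases
    capture_mult_privileged: float = 0.95  # and Q1/Q2 (higher-SES) cases
    p_surgery: float = 0.80
    p_chemo_radio: float = 0.60
    claim_count_mean: float = 3.0  # extra CRC claims beyond the first, Poisson
    claim_horizon_days: int = 180
    p_registry_site_unspecified: float = 0.0022
    p_ruleout: float = 0.005  # non-case emits CRC-coded claims at all
    p_ruleout_pair: float = 0.10  # ...and those claims form a qualifying pair
    background_claims_mean: float = 2.0  # non-CRC claims per person, Poisson
    edge_censoring: bool = False  # True: drop the end-of-period guard

    def __post_init__(self) -> None:
        for name, dist in (("age_mix", self.age_mix), ("quintile_mix", self.quintile_mix)):
            if abs(sum(dist) - 1) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if len(self.age_mix) != len(AGE_BANDS) or len(self.incidence_per_1e5) != len(AGE_BANDS):
            raise ValueError(f"age_mix and incidence need {len(AGE_BANDS)} bands")
        probs = (
            self.female_share, self.p_hospitalized, self.p_capture_hospitalized,
            self.p_capture_outpatient, self.p_surgery, self.p_chemo_radio,
            self.p_ruleout, self.p_ruleout_pair, self.colon_share,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if max(self.incidence_per_1e5) >= 1e5:
            raise ValueError("incidence exceeds population")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator keyed by (seed, crc32(name))."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _ts(d: date) -> np.datetime64:
    return np.datetime64(d, "D")


def _completed_years(birth: pd.Series, at: pd.Series | pd.Timestamp) -> np.ndarray:
    """Vectorized calendar age in completed years."""
    if isinstance(at, pd.Timestamp):
        at_y, at_m, at_d = at.year, at.month, at.day
    else:
        at_y, at_m, at_d = at.dt.year, at.dt.month, at.dt.day
    years = at_y - birth.dt.year.to_numpy()
    before = (birth.dt.month.to_numpy() > np.asarray(at_m)) | (
        (birth.dt.month.to_numpy() == np.asarray(at_m)) & (birth.dt.day.to_numpy() > np.asarray(at_d))
    )
    return np.asarray(years) - before.astype(int)


def simulate(config: SimulationConfig | None = None, seed: int = 0) -> tuple[LinkedDataset, pd.DataFrame]:
    """Generate a linked synthetic dataset plus its ground-truth table.

    Returns a validated :class:`LinkedDataset` and a truth DataFrame with one
    row per person: ``is_case``, ``true_diagnosis_date``, ``true_site``,
    ``hospitalized``, ``registry_captured``, ``treated``.
    """
    cfg = config or SimulationConfig()
    period = cfg.period
    n = cfg.n_persons

    # --- persons -----------------------------------------------------------
    rng = _rng(seed, "persons")
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(cfg.age_mix))
    lo = np.array([b[0] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[1] for b in AGE_BANDS])[band_idx]
    # age in completed years at period start, uniform within band; birth dates
    # chosen so the calendar completed-years age at period start is exact
    age0 = rng.integers(lo, hi + 1)
    doy = rng.integers(1, 366, n)  # birthday as day-of-year, leap day avoided
    # day-of-year comparison in a fixed non-leap calendar (2001) so the
    # completed-years age at period start comes out exactly age0
    start_doy = pd.Timestamp(2001, period.start.month, period.start.day).dayofyear
    birth_year = np.where(doy <= start_doy, period.start.year - age0, period.start.year - age0 - 1)
    birth = pd.to_datetime(
        pd.Series(birth_year * 1000 + doy).astype(str), format="%Y%j"
    )
    start = _ts(period.start)
    sex = np.where(rng.random(n) < cfg.female_share, "female", "male")
    quintile = rng.choice([1, 2, 3, 4, 5], size=n, p=np.asarray(cfg.quintile_mix))
    person_id = np.array([f"P{i:07d}" for i in range(n)])

    # --- incident cases via person-year hazards ---------------------------
    # Bernoulli per person per calendar-year slice of the period, with the
    # per-band annual risk; the first success is the true diagnosis.
    rng = _rng(seed, "cases")
    lam = np.asarray(cfg.incidence_per_1e5, float) / 1e5
    last_allowed = period.end if cfg.edge_censoring else period.end - timedelta(days=cfg.claim_horizon_days)
    is_case = np.zeros(n, dtype=bool)
    true_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    for year in range(period.start.year, period.end.year + 1):
        y0, y1 = date(year, 1, 1), date(year, 12, 31)
        w0, w1 = max(y0, period.start), min(y1, last_allowed)
        if w0 > w1:
            continue
        ndays = (w1 - w0).days + 1
        mid = pd.Timestamp(w0) + pd.Timedelta(days=ndays // 2)
        age_now = _completed_years(birth, mid)
        band_now = np.clip((age_now - 20) // 5, 0, len(AGE_BANDS) - 1)
        p = lam[band_now] * (ndays / 365.25)
        hit = (~is_case) & (rng.random(n) < p)
        offs = rng.integers(0, ndays, n)  # drawn unconditionally: stream stability
        true_date[hit] = _ts(w0) + offs[hit] * _DAY
        is_case |= hit

    case_ix = np.flatnonzero(is_case)
    n_cases = case_ix.size

    rng = _rng(seed, "case-attrs")
    true_site = np.where(rng.random(n_cases) < cfg.colon_share, Site.COLON.value, Site.RECTUM.value)
    hospitalized = rng.random(n_cases) < cfg.p_hospitalized
    surg = rng.random(n_cases) < cfg.p_surgery
    chemo = rng.random(n_cases) < cfg.p_chemo_radio
    treated = surg | chemo
    age_at_dx = _completed_years(
        birth.iloc[case_ix].reset_index(drop=True),
        pd.Series(pd.to_datetime(true_date[case_ix])),
    )
    p_cap = np.where(hospitalized, cfg.p_capture_hospitalized, cfg.p_capture_outpatient)
    p_cap = p_cap * np.where(age_at_dx < 50, cfg.capture_mult_under50, 1.0)
    p_cap = p_cap * np.where(quintile[case_ix] <= 2, cfg.capture_mult_privileged, 1.0)
    registry_captured = rng.random(n_cases) < p_cap

    end_ts = _ts(period.end)

    def _clamp(dates: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(dates, start), end_ts)

    # --- hospital admissions ----------------------------------------------
    rng = _rng(seed, "admissions")
    adm_pid, adm_date, adm_disc, adm_dx, adm_ver, adm_interv = [], [], [], [], [], []
    hosp_ix = case_ix[hospitalized]
    hosp_site = true_site[hospitalized]
    los = rng.integers(3, 15, hosp_ix.size)
    for j, pix in enumerate(hosp_ix):
        d = true_date[pix]
        code = "C18.9" if hosp_site[j] == Site.COLON.value else "C20"
        adm_pid.append(person_id[pix])
        adm_date.append(d)
        adm_disc.append(min(d + int(los[j]) * _DAY, end_ts))
        adm_dx.append(f"{code}|I10")  # CRC plus an unrelated comorbidity code
        adm_ver.append("ICD10|ICD10")
        adm_interv.append("")

    # --- billing: outpatient CRC diagnostic claims for every case ---------
    rng = _rng(seed, "claims")
    bill_pid, bill_date, bill_dx, bill_ver, bill_act = [], [], [], [], []
    k_extra = rng.poisson(cfg.claim_count_mean, n_cases)
    for j, pix in enumerate(case_ix):
        d0 = true_date[pix]
        code = "153.9" if true_site[j] == Site.COLON.value else "154.1"
        dates = [d0] + [
            d0 + int(o) * _DAY
            for o in rng.integers(1, cfg.claim_horizon_days + 1, k_extra[j])
        ]
        for d in dates:
            bill_pid.append(person_id[pix])
            bill_date.append(_clamp(d))
            bill_dx.append(code)
            bill_ver.append("ICD9")
            bill_act.append("")

    # --- billing: treatment act claims ------------------------------------
    rng = _rng(seed, "treatment")
    tx_codes = {"surgery": ("SURG-COLECT", "SURG-LAR"), "chemo": ("CHEMO-FOLFOX", "RADIO-PELV")}
    for j, pix in enumerate(case_ix):
        d0 = true_date[pix]
        for flag, key in ((surg[j], "surgery"), (chemo[j], "chemo")):
            if flag:
                code = tx_codes[key][int(rng.integers(0, 2))]
                offset = int(rng.integers(7, cfg.claim_horizon_days + 1))
                bill_pid.append(person_id[pix])
                bill_date.append(_clamp(d0 + offset * _DAY))
                bill_dx.append("")
                bill_ver.append("")
                bill_act.append(code)

    # --- registry ----------------------------------------------------------
    rng = _rng(seed, "registry")
    reg_pid, reg_date, reg_site = [], [], []
    cap_ix = case_ix[registry_captured]
    cap_site = true_site[registry_captured]
    noise = rng.integers(-14, 31, cap_ix.size)
    unspec = rng.random(cap_ix.size) < cfg.p_registry_site_unspecified
    for j, pix in enumerate(cap_ix):
        reg_pid.append(person_id[pix])
        reg_date.append(_clamp(true_date[pix] + int(noise[j]) * _DAY))
        reg_site.append(Site.UNSPECIFIED.value if unspec[j] else cap_site[j])

    # --- rule-out noise from non-cases -------------------------------------
    rng = _rng(seed, "ruleout")
    noncase_ix = np.flatnonzero(~is_case)
    emits = rng.random(noncase_ix.size) < cfg.p_ruleout
    pairs = rng.random(noncase_ix.size) < cfg.p_ruleout_pair
    span = (period.end - period.start).days - 150
    offs = rng.integers(0, span, noncase_ix.size)
    gaps = rng.integers(30, 121, noncase_ix.size)
    for j in np.flatnonzero(emits):
        pix = noncase_ix[j]
        d0 = start + int(offs[j]) * _DAY
        bill_pid.append(person_id[pix])
        bill_date.append(d0)
        bill_dx.append("153.9")
        bill_ver.append("ICD9")
        bill_act.append("")
        if pairs[j]:
            bill_pid.append(person_id[pix])
            bill_date.append(_clamp(d0 + int(gaps[j]) * _DAY))
            bill_dx.append("153.9")
            bill_ver.append("ICD9")
            bill_act.append("")

    # --- background non-CRC claims -----------------------------------------
    rng = _rng(seed, "background")
    n_bg = rng.poisson(cfg.background_claims_mean, n)
    total_days = (period.end - period.start).days
    for pix in np.flatnonzero(n_bg > 0):
        for o in rng.integers(0, total_days + 1, n_bg[pix]):
            bill_pid.append(person_id[pix])
            bill_date.append(start + int(o) * _DAY)
            bill_dx.append("401.9")
            bill_ver.append("ICD9")
            bill_act.append("")

    # --- assemble ----------------------------------------------------------
    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "birth_date": pd.to_datetime(birth),
            "sex": sex,
            "deprivation_quintile": quintile.astype(int),
            "death_date": pd.NaT,
        }
    )
    billing = pd.DataFrame(
        {
            "person_id": bill_pid,
            "service_date": pd.to_datetime(np.array(bill_date, dtype="datetime64[D]")),
            "dx_code": pd.array(bill_dx, dtype="object"),
            "dx_version": bill_ver,
            "act_code": pd.array(bill_act, dtype="object"),
        }
    ).sort_values(["person_id", "service_date"], kind="stable").reset_index(drop=True)
    billing = billing.replace({"": None})
    admissions = pd.DataFrame(
        {
            "person_id": adm_pid,
            "admission_date": pd.to_datetime(np.array(adm_date, dtype="datetime64[D]")),
            "discharge_date": pd.to_datetime(np.array(adm_disc, dtype="datetime64[D]")),
            "dx_codes": adm_dx,
            "dx_versions": adm_ver,
            "intervention_codes": pd.array(adm_interv, dtype="object"),
        }
    ).sort_values(["person_id", "admission_date"], kind="stable").reset_index(drop=True)
    admissions = admissions.replace({"": None})
    registry = pd.DataFrame(
        {
            "person_id": reg_pid,
            "diagnosis_date": pd.to_datetime(np.array(reg_date, dtype="datetime64[D]")),
            "site": reg_site,
        }
    ).sort_values("person_id", kind="stable").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "is_case": is_case,
            "true_diagnosis_date": pd.to_datetime(true_date),
            "true_site": pd.array(
                [None] * n, dtype="object"
            ),
            "hospitalized": False,
            "registry_captured": False,
            "treated": False,
        }
    )
    truth.loc[case_ix, "true_site"] = true_site
    truth.loc[case_ix, "hospitalized"] = hospitalized
    truth.loc[case_ix, "registry_captured"] = registry_captured
    truth.loc[case_ix, "treated"] = treated

    dataset = LinkedDataset(
        persons=persons,
        billing=billing,
        admissions=admissions,
        registry=registry,
        period=period,
    )
    return dataset, truth


def summarize_truth(truth: pd.DataFrame, cases: list[CandidateCase]) -> dict[str, float]:
    """Validation metrics for one algorithm's output against ground truth.

    Sensitivity is the share of true cases detected; false positives are
    detected persons who are not true cases; the date error is assigned
    minus true diagnosis date, in days, summarized over true-positive cases.
    """
    true_ids = set(truth.loc[truth["is_case"], "person_id"])
    detected = {c.person_id: c for c in cases}
    tp = set(detected) & true_ids
    fp = set(detected) - true_ids
    errors = []
    true_dates = truth.set_index("person_id")["true_diagnosis_date"]
    for pid in tp:
        err = (pd.Timestamp(detected[pid].diagnosis_date) - true_dates[pid]).days
        errors.append(err)
    errors = np.asarray(errors, float) if errors else np.array([np.nan])
    return {
        "n_true_cases": len(true_ids),
        "n_detected": len(detected),
        "sensitivity": len(tp) / len(true_ids) if true_ids else float("nan"),
        "false_positives": len(fp),
        "date_error_mean_days": float(np.nanmean(errors)),
        "date_error_abs_p90_days": float(np.nanpercentile(np.abs(errors), 90)),
    }


def write_dataset_csv(dataset: LinkedDataset, outdir: str | Path, truth: pd.DataFrame | None = None) -> None:
    """Write the four linked tables (and optionally truth) as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _iso(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        out = df.copy()
        for c in cols:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        return out

    _iso(dataset.persons, ["birth_date", "death_date"]).to_csv(outdir / "persons.csv", index=False)
    _iso(dataset.billing, ["service_date"]).to_csv(outdir / "billing.csv", index=False)
    _iso(dataset.admissions, ["admission_date", "discharge_date"]).to_csv(
        outdir / "admissions.csv", index=False
    )
    _iso(dataset.registry, ["diagnosis_date"]).to_csv(outdir / "registry.csv", index=False)
    if truth is not None:
        _iso(truth, ["true_diagnosis_date"]).to_csv(outdir / "truth.csv", index=False)
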