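"""Synthetic multi-facility inpatient cohorts with known NV-HAP dynamics.

The generator emulates the structure an electronic surveillance definition
needs — multi-facility admissions, daily oxygenation/vitals/labs
trajectories, covariate-dependent pneumonia onset, and competing
inpatient-death / alive-discharge hazards — with ground truth written to a
separate table so detector and estimator can be scored against it.

The generative model, per admission and hospital day ``t``:

* From day 3, while event-free and not ventilated at baseline, NV-HAP onset
  is drawn from a per-day logistic model on lag-2 covariates (age,
  comorbidity index, ICU status two days prior, last creatinine measured at
  or before ``t-2``), plus a facility-level intercept.
* Death and alive-discharge are competing per-day Bernoulli hazards.  Once
  NV-HAP is present the death hazard is multiplied by ``theta_death`` and
  the discharge hazard by ``theta_discharge`` (both 1 = no effect).  A
  severity multiplier (age, comorbidity index, current ICU) scales the death
  hazard, so onset and death share causes: confounding is real.
* For each true event the surveillance signature is written into the tables:
  a device escalation or an SpO2 drop on the onset day and the next day
  (always), and fever-or-leukocytosis, chest imaging, and a 3-day new
  antimicrobial run each with probability ``signal_completeness``.

Terminal events are suppressed on the onset day and the following day and
onset is never drawn after ``max_followup - 2``, so every true event's
signature window fits inside the stay.  ICU trajectories are exogenous (not
altered by onset): ``theta_death`` is the *only* pathway from NV-HAP to
death, which is what makes the theta=1 null exactly recoverable.

Same seed + config => byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import ehr_model as em
from .ehr_model import Dataset, IntegrityError

__all__ = ["SimConfig", "ConfigError", "generate", "plant_fixture"]


class ConfigError(ValueError):
    """Simulation configuration is infeasible."""


def _default_onset_coefficients() -> dict:
    return {
        "intercept": -6.3,
        "age_per_10y": 0.25,
        "elixhauser": 0.06,
        "icu_lag2": 0.8,
        "creatinine_lag2": 0.25,
    }


def _default_death_severity() -> dict:
    return {"age_per_10y": 0.25, "elixhauser": 0.04, "icu": 0.5}


@dataclass
class SimConfig:
    """Conditions of one simulated cohort.

    Defaults emulate a general acute-care population: ~0.5-1 true events per
    100 admissions, median stay ~4 days, ~2% inpatient mortality, with
    NV-HAP doubling the death hazard and halving the discharge hazard.
    """

    n_facilities: int = 20
    n_hospitalizations: int = 5000
    seed: int = 0
    baseline_death_hazard: float = 0.004
    baseline_discharge_hazard: float = 0.22
    nvhap_onset_coefficients: dict = field(default_factory=_default_onset_coefficients)
    theta_death: float = 2.0
    theta_discharge: float = 0.5
    signal_completeness: float = 0.9
    max_followup: int = 90
    # artifact knobs beyond the core model
    background_noise: float = 1.0  # scales SpO2 jitter and background signature rates
    facility_onset_sd: float = 0.25  # SD of facility-level onset log-odds
    lab_day1_p: float = 0.95  # P(routine lab panel measured) on day 1
    lab_daily_p: float = 0.7  # ... on later days
    spo2_jitter_sd: float = 0.8  # day-to-day SpO2 noise, percentage points
    signature_spo2_drop: float = 6.0  # SpO2 drop written for spo2-route events
    death_severity_coefficients: dict = field(default_factory=_default_death_severity)

    def validate(self) -> "SimConfig":
        for name in ("baseline_death_hazard", "baseline_discharge_hazard"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.theta_death <= 0 or self.theta_discharge <= 0:
            raise ConfigError("theta parameters must be > 0")
        worst = (
            self.baseline_death_hazard * max(self.theta_death, 1.0)
            + self.baseline_discharge_hazard * max(self.theta_discharge, 1.0)
        )
        if worst >= 1:
            raise ConfigError(f"per-day hazard sum {worst:.3f} >= 1 is infeasible")
        if not 0 <= self.signal_completeness <= 1:
            raise ConfigError("signal_completeness must be in [0,1]")
        if self.max_followup < 5:
            raise ConfigError("max_followup must be >= 5")
        if self.n_hospitalizations < 0 or self.n_facilities < 1:
            raise ConfigError("counts must be nonnegative (>=1 facility)")
        return self


# ---------------------------------------------------------------------------
# population constants (marginal frequencies of a general inpatient mix)
# ---------------------------------------------------------------------------

_BED_P = [0.37, 0.29, 0.16, 0.18]
_REGION_P = [0.16, 0.11, 0.56, 0.17]
_TEACHING_P = 0.70
_FEMALE_P = 0.304
_RACE_P = [0.014, 0.186, 0.704, 0.096]
_SERVICE_P = [0.031, 0.581, 0.271, 0.009, 0.005, 0.103]
_COMORBIDITY_P = [0.161, 0.169, 0.326, 0.057, 0.093, 0.134, 0.181]
# van Walraven-style weights for the seven flags carried here
_VW_WEIGHTS = np.array([7, 3, 0, 11, 9, 6, 5], dtype=float)
_DEVICE_BASELINE_P = [0.78, 0.16, 0.02, 0.005, 0.005, 0.015, 0.01, 0.005]

_LAB_LEVELS = {  # (log-median, log-sd) or (mean, sd) for sodium/hematocrit
    "wbc": (np.log(8.0), 0.30),
    "platelets": (np.log(230.0), 0.35),
    "glucose": (np.log(130.0), 0.30),
    "alt": (np.log(25.0), 0.60),
    "bilirubin": (np.log(0.7), 0.50),
}


def _choice(rng: np.random.Generator, p: Sequence[float], n: int) -> np.ndarray:
    """Categorical draw by inverse CDF (stable draw count for determinism)."""
    cum = np.cumsum(p) / np.sum(p)
    return np.searchsorted(cum, rng.random(n), side="right").clip(0, len(p) - 1)


def _empty_dataset() -> tuple[Dataset, pd.DataFrame]:
    ds = Dataset(
        facilities=pd.DataFrame(columns=list(em.FACILITY_SCHEMA)),
        hospitalizations=pd.DataFrame(columns=list(em.HOSPITALIZATION_SCHEMA)),
        daily=pd.DataFrame(columns=list(em.DAILY_SCHEMA)),
        medications=pd.DataFrame(columns=list(em.MEDICATION_SCHEMA)),
    )
    truth = pd.DataFrame(columns=["hosp_id", "true_nvhap_day", "true_cause"])
    return ds, truth


def generate(config: SimConfig) -> tuple[Dataset, pd.DataFrame]:
    """Simulate a cohort; returns ``(dataset, ground_truth)``.

    Ground truth has one row per admission: ``true_nvhap_day`` (nullable) and
    ``true_cause`` in {death, discharge, censored}; it is never written into
    the analysis tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_hospitalizations
    T = config.max_followup
    noise = config.background_noise

    # --- facilities -------------------------------------------------------
    nf = config.n_facilities
    fac_ids = np.array([f"F{i + 1:03d}" for i in range(nf)])
    facilities = pd.DataFrame(
        {
            "facility_id": fac_ids,
            "bed_size_class": np.array(em.BED_SIZE_CLASSES)[_choice(rng, _BED_P, nf)],
            "teaching": rng.random(nf) < _TEACHING_P,
            "region": np.array(em.REGIONS)[_choice(rng, _REGION_P, nf)],
        }
    )
    fac_weights = rng.dirichlet(np.full(nf, 5.0))
    fac_onset_shift = rng.normal(0.0, config.facility_onset_sd, nf)

    if n == 0:
        ds, truth = _empty_dataset()
        ds.facilities = facilities
        return ds, truth

    # --- admission-level covariates --------------------------------------
    hosp_ids = np.array([f"H{i + 1:06d}" for i in range(n)])
    fac_idx = _choice(rng, fac_weights, n)
    age = np.clip(np.round(rng.normal(64.0, 15.0, n)), 18, 100).astype(int)
    female = rng.random(n) < _FEMALE_P
    race = np.array(em.RACES)[_choice(rng, _RACE_P, n)]
    flags = rng.random((n, len(em.COMORBIDITY_FLAGS))) < np.array(_COMORBIDITY_P)
    elix = (flags @ _VW_WEIGHTS + np.round(rng.normal(0.0, 2.0, n))).astype(int)
    prior_90d = rng.random(n) < 0.2
    service = np.array(em.SERVICES)[_choice(rng, _SERVICE_P, n)]
    admit = pd.to_datetime("2019-01-01") + pd.to_timedelta(
        rng.integers(0, 365, n), unit="D"
    )

    age_c = (age - 65.0) / 10.0
    # exogenous ICU path: an initial ICU block whose odds rise with severity
    icu_p = expit(-2.3 + 0.05 * elix + 0.15 * age_c)
    icu_start = rng.random(n) < icu_p
    icu_len = np.where(icu_start, 1 + rng.geometric(0.45, n), 0)
    days_grid = np.arange(1, T + 1)
    icu_arr = days_grid[None, :] <= icu_len[:, None]  # (n, T)

    baseline_rank = _choice(rng, _DEVICE_BASELINE_P, n)
    base_spo2 = np.clip(np.round(rng.normal(96.5, 1.0, n)), 88, 100)

    # routine lab panel measurement days and the creatinine path (creatinine
    # feeds the onset hazard, so its realized values are fixed here)
    lab_mask = rng.random((n, T)) < config.lab_daily_p
    lab_mask[:, 0] = rng.random(n) < config.lab_day1_p
    creat_level = np.exp(rng.normal(0.0, 0.35, n)) * (1 + 0.02 * np.maximum(elix, 0))
    creat_vals = np.round(
        creat_level[:, None] * np.exp(rng.normal(0.0, 0.08, (n, T))), 2
    )

    # lag-2 LOCF creatinine as the analyst will see it (population normal
    # value 1.0 where nothing has been measured yet)
    creat_locf = np.full((n, T), np.nan)
    last = np.full(n, np.nan)
    for t in range(T):
        last = np.where(lab_mask[:, t], creat_vals[:, t], last)
        creat_locf[:, t] = last
    creat_lag2 = np.full((n, T), 1.0)
    creat_lag2[:, 2:] = np.where(
        np.isnan(creat_locf[:, :-2]), 1.0, creat_locf[:, :-2]
    )
    icu_lag2 = np.zeros((n, T), dtype=bool)
    icu_lag2[:, 2:] = icu_arr[:, :-2]

    # --- per-day hazards ---------------------------------------------------
    c = config.nvhap_onset_coefficients
    lp = (
        c.get("intercept", -6.3)
        + c.get("age_per_10y", 0.0) * age_c[:, None]
        + c.get("elixhauser", 0.0) * elix[:, None]
        + c.get("icu_lag2", 0.0) * icu_lag2
        + c.get("creatinine_lag2", 0.0) * (creat_lag2 - 1.0)
        + fac_onset_shift[fac_idx][:, None]
    )
    p_onset = expit(lp)

    sev = config.death_severity_coefficients
    m_static = np.exp(
        sev.get("age_per_10y", 0.0) * age_c + sev.get("elixhauser", 0.0) * elix
    )
    icu_mult = np.exp(sev.get("icu", 0.0))

    u_onset = rng.random((n, T))
    u_exit = rng.random((n, T))

    onset = np.zeros(n, dtype=int)  # 0 = no event
    exit_day = np.zeros(n, dtype=int)
    cause = np.full(n, "censored", dtype=object)
    active = np.ones(n, dtype=bool)
    can_onset = baseline_rank < em.OXYGEN_DEVICES.index("ventilator")

    for t in range(1, T + 1):
        j = t - 1
        if 3 <= t <= T - 2:
            new = active & can_onset & (onset == 0) & (u_onset[:, j] < p_onset[:, j])
            onset[new] = t
        post = (onset > 0) & (onset <= t)
        suppress = (onset > 0) & (t <= onset + 1)
        p_d = (
            config.baseline_death_hazard
            * np.where(post, config.theta_death, 1.0)
            * m_static
            * np.where(icu_arr[:, j], icu_mult, 1.0)
        )
        p_c = config.baseline_discharge_hazard * np.where(
            post, config.theta_discharge, 1.0
        )
        total = p_d + p_c
        scale = np.minimum(1.0, 0.95 / np.maximum(total, 1e-12))
        p_d, p_c = p_d * scale, p_c * scale
        p_d[suppress] = 0.0
        p_c[suppress] = 0.0
        death = active & (u_exit[:, j] < p_d)
        disc = active & ~death & (u_exit[:, j] < p_d + p_c)
        done = death | disc
        exit_day[done] = t
        cause[death] = "death"
        cause[disc] = "discharge"
        active &= ~done
    exit_day[active] = T  # administratively censored stays
    los = exit_day

    # --- dispositions ------------------------------------------------------
    disposition = np.full(n, "other", dtype=object)
    disposition[cause == "death"] = "death"
    u_disp = rng.random(n)
    alive = cause == "discharge"
    post_ev = alive & (onset > 0)
    plain = alive & (onset == 0)
    alive_cats = np.array(["home", "skilled_nursing", "rehabilitation", "hospice", "other"])
    p_plain = np.cumsum([0.85, 0.08, 0.02, 0.01, 0.04])
    p_post = np.cumsum([0.45, 0.25, 0.07, 0.12, 0.11])
    disposition[plain] = alive_cats[np.searchsorted(p_plain, u_disp[plain]).clip(0, 4)]
    disposition[post_ev] = alive_cats[np.searchsorted(p_post, u_disp[post_ev]).clip(0, 4)]

    # --- daily table --------------------------------------------------------
    total_rows = int(los.sum())
    hosp_idx = np.repeat(np.arange(n), los)
    offsets = np.concatenate([[0], np.cumsum(los)[:-1]])
    day = np.arange(total_rows) - np.repeat(offsets, los) + 1

    temp_min = np.round(rng.normal(36.4, 0.2, total_rows), 1)
    temp_max = np.round(temp_min + 0.4 + np.abs(rng.normal(0.0, 0.25, total_rows)), 1)
    bg_fever = rng.random(total_rows) < 0.02 * noise
    temp_max = np.where(
        bg_fever, np.round(38.1 + rng.exponential(0.4, total_rows), 1), temp_max
    )

    measured = lab_mask[hosp_idx, day - 1]
    labs: dict[str, np.ndarray] = {}
    labs["creatinine"] = np.where(measured, creat_vals[hosp_idx, day - 1], np.nan)
    for name, (mu, sd) in _LAB_LEVELS.items():
        if name in ("alt", "bilirubin"):
            continue
        level = np.exp(rng.normal(mu, sd, n))
        vals = level[hosp_idx] * np.exp(rng.normal(0.0, 0.08, total_rows))
        digits = 1 if name == "wbc" else 0
        labs[name] = np.where(measured, np.round(vals, digits), np.nan)
    for name, (mean, sd, digits) in {
        "hematocrit": (35.0, 5.0, 1),
        "sodium": (138.0, 3.0, 0),
    }.items():
        level = rng.normal(mean, sd, n)
        vals = level[hosp_idx] + rng.normal(0.0, 1.0, total_rows)
        labs[name] = np.where(measured, np.round(vals, digits), np.nan)

    nonroutine_p = np.where(day == 1, 0.5, 0.25)
    nr_mask = rng.random(total_rows) < nonroutine_p
    for name, (mu, sd) in (("alt", _LAB_LEVELS["alt"]), ("bilirubin", _LAB_LEVELS["bilirubin"])):
        level = np.exp(rng.normal(mu, sd, n))
        vals = level[hosp_idx] * np.exp(rng.normal(0.0, 0.10, total_rows))
        labs[name] = np.where(nr_mask, np.round(vals, 1), np.nan)
    alb_level = rng.normal(3.8, 0.5, n)
    labs["albumin"] = np.where(
        nr_mask, np.round(alb_level[hosp_idx] + rng.normal(0.0, 0.1, total_rows), 1), np.nan
    )

    spo2 = np.clip(
        np.round(
            base_spo2[hosp_idx] + rng.normal(0.0, config.spo2_jitter_sd * noise, total_rows)
        ),
        70,
        100,
    )
    dev_rank = baseline_rank[hosp_idx].astype(int).copy()
    imaging = rng.random(total_rows) < np.where(day == 1, 0.25 * noise, 0.02 * noise)

    med_hosp: list[np.ndarray] = []
    med_day: list[np.ndarray] = []
    med_agent: list[str] = []

    # background antimicrobial courses
    bg_course = rng.random(n) < 0.15 * noise
    bg_start = np.floor(rng.random(n) * los).astype(int) + 1
    bg_len = 1 + rng.geometric(0.45, n)
    for i in np.flatnonzero(bg_course):
        d0, d1 = bg_start[i], min(bg_start[i] + bg_len[i] - 1, los[i])
        ds_ = np.arange(d0, d1 + 1)
        med_hosp.append(np.full(len(ds_), i))
        med_day.append(ds_)
        med_agent.extend(["abx_background"] * len(ds_))

    # --- surveillance signatures for true events ---------------------------
    sc = config.signal_completeness
    for i in np.flatnonzero(onset > 0):
        o, L, off = int(onset[i]), int(los[i]), int(offsets[i])
        sig_days = np.arange(o, min(o + 2, L) + 1)  # onset day .. +2 (>= 2 days)
        rows = off + sig_days - 1
        if rng.random() < 0.7:  # device-escalation route
            dev_rank[rows] = min(int(baseline_rank[i]) + 2, 7)
        else:  # desaturation route
            spo2[rows] = np.maximum(70, spo2[rows] - config.signature_spo2_drop)
        if rng.random() < sc:  # fever or leukocytosis
            if rng.random() < 0.7:
                temp_max[off + o - 1] = round(38.3 + abs(rng.normal(0.0, 0.4)), 1)
            else:
                labs["wbc"][off + o - 1] = round(13.0 + rng.exponential(3.0), 1)
        if rng.random() < sc:
            imaging[off + o - 1] = True
        if rng.random() < sc:
            ds_ = np.arange(o, o + 3)  # los >= o+2 is guaranteed
            med_hosp.append(np.full(3, i))
            med_day.append(ds_)
            med_agent.extend(["abx_treatment"] * 3)

    daily = pd.DataFrame(
        {
            "hosp_id": hosp_ids[hosp_idx],
            "day": day.astype(np.int64),
            "service": service[hosp_idx],
            "icu": icu_arr[hosp_idx, day - 1],
            "temp_min": temp_min,
            "temp_max": temp_max,
            "wbc": labs["wbc"],
            "spo2_min": spo2.astype(float),
            "o2_device": np.array(em.OXYGEN_DEVICES, dtype=object)[dev_rank],
            "hematocrit": labs["hematocrit"],
            "platelets": labs["platelets"],
            "sodium": labs["sodium"],
            "glucose": labs["glucose"],
            "creatinine": labs["creatinine"],
            "alt": labs["alt"],
            "bilirubin": labs["bilirubin"],
            "albumin": labs["albumin"],
            "chest_imaging": imaging,
        }
    )

    if med_hosp:
        mh = np.concatenate(med_hosp)
        medications = pd.DataFrame(
            {
                "hosp_id": hosp_ids[mh],
                "day": np.concatenate(med_day).astype(np.int64),
                "agent_id": np.array(med_agent, dtype=object),
            }
        ).sort_values(["hosp_id", "day", "agent_id"], kind="stable").reset_index(drop=True)
    else:
        medications = pd.DataFrame(columns=list(em.MEDICATION_SCHEMA))

    hospitalizations = pd.DataFrame(
        {
            "hosp_id": hosp_ids,
            "facility_id": fac_ids[fac_idx],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "race": race,
            "admit_day": admit.strftime("%Y-%m-%d"),
            "los": los.astype(np.int64),
            "disposition": disposition,
            **{
                flag: flags[:, k]
                for k, flag in enumerate(em.COMORBIDITY_FLAGS)
            },
            "elixhauser_index": elix,
            "prior_90d_admission": prior_90d,
        }
    )

    truth = pd.DataFrame(
        {
            "hosp_id": hosp_ids,
            "true_nvhap_day": pd.array(
                np.where(onset > 0, onset, np.nan), dtype="Int64"
            ),
            "true_cause": cause,
        }
    )
    dataset = Dataset(
        facilities=facilities,
        hospitalizations=hospitalizations,
        daily=daily,
        medications=medications,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# deterministic single-admission fixtures for rule-engine tests
# ---------------------------------------------------------------------------

_DAY_DEFAULTS = {
    "service": "medicine",
    "icu": False,
    "temp_min": 36.5,
    "temp_max": 37.0,
    "wbc": 8.0,
    "spo2": 97.0,
    "device": "none",
    "hematocrit": 35.0,
    "platelets": 250.0,
    "sodium": 138.0,
    "glucose": 110.0,
    "creatinine": 1.0,
    "alt": None,
    "bilirubin": None,
    "albumin": None,
    "imaging": False,
}


def plant_fixture(
    days: Sequence[Mapping],
    hosp_id: str = "H000001",
    facility_id: str = "F001",
    age: int = 70,
    sex: str = "male",
    race: str = "White",
    disposition: str = "home",
    elixhauser_index: int = 3,
    **hosp_overrides,
) -> Dataset:
    """Build a single-admission dataset from an explicit per-day trajectory.

    Each entry of ``days`` describes one hospital day; recognised keys are
    ``device, spo2, temp_min, temp_max, wbc, imaging, agents, icu, service``
    plus any lab name.  An optional ``day`` key must equal the 1-based
    position (duplicates or gaps raise :class:`IntegrityError`).  No
    randomness: the emitted tables are exactly the specification.
    """
    if not days:
        raise IntegrityError("fixture needs at least one day")
    seen = []
    for pos, spec_day in enumerate(days, start=1):
        d = spec_day.get("day", pos)
        seen.append(int(d))
    if seen != list(range(1, len(days) + 1)):
        raise IntegrityError(f"fixture days must be contiguous 1..los, got {seen}")

    daily_rows, med_rows = [], []
    for pos, spec_day in enumerate(days, start=1):
        merged = {**_DAY_DEFAULTS, **{k: v for k, v in spec_day.items() if k != "day" and k != "agents"}}
        daily_rows.append(
            {
                "hosp_id": hosp_id,
                "day": pos,
                "service": merged["service"],
                "icu": bool(merged["icu"]),
                "temp_min": merged["temp_min"],
                "temp_max": merged["temp_max"],
                "wbc": merged["wbc"],
                "spo2_min": merged["spo2"],
                "o2_device": merged["device"],
                "hematocrit": merged["hematocrit"],
                "platelets": merged["platelets"],
                "sodium": merged["sodium"],
                "glucose": merged["glucose"],
                "creatinine": merged["creatinine"],
                "alt": merged["alt"],
                "bilirubin": merged["bilirubin"],
                "albumin": merged["albumin"],
                "chest_imaging": bool(merged["imaging"]),
            }
        )
        for agent in spec_day.get("agents", ()):
            med_rows.append({"hosp_id": hosp_id, "day": pos, "agent_id": agent})

    facilities = pd.DataFrame(
        [{"facility_id": facility_id, "bed_size_class": "100-199", "teaching": True, "region": "South"}]
    )
    hosp = {
        "hosp_id": hosp_id,
        "facility_id": facility_id,
        "age": age,
        "sex": sex,
        "race": race,
        "admit_day": "2019-06-01",
        "los": len(days),
        "disposition": disposition,
        **{flag: False for flag in em.COMORBIDITY_FLAGS},
        "elixhauser_index": elixhauser_index,
        "prior_90d_admission": False,
    }
    hosp.update(hosp_overrides)
    hospitalizations = pd.DataFrame([hosp])
    daily = pd.DataFrame(daily_rows, columns=list(em.DAILY_SCHEMA))
    for col, kind in em.DAILY_SCHEMA.items():
        if kind == "float":
            daily[col] = pd.to_numeric(daily[col], errors="coerce").astype(float)
    medications = pd.DataFrame(med_rows, columns=list(em.MEDICATION_SCHEMA))
    return Dataset(
        facilities=facilities,
        hospitalizations=hospitalizations,
        daily=daily,
        medications=medications,
    )
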