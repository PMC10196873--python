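"""Shared fixtures: planted trajectories and simulated cohorts.

The heavy session fixtures use a deliberately high-acuity cohort
configuration (per-day onset log-odds intercept -3.9, baseline death hazard
0.01/day) so that estimator properties are resolvable at n=20 000; see
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nvhap import (
    SimConfig,
    build_person_days,
    detect_all,
    detect_nvhap,
    eligible_cohort,
    estimate_attributable,
    generate,
    impute_normal_oxygenation,
    plant_fixture,
    weighted_aalen_johansen,
)
from nvhap.ehr_model import Dataset
from nvhap.surveillance import SurveillanceParams

# cohort used for estimator validation (null recovery, effect direction)
VALIDATION_KW = dict(
    n_facilities=12,
    n_hospitalizations=20_000,
    baseline_death_hazard=0.010,
    baseline_discharge_hazard=0.22,
    nvhap_onset_coefficients={
        "intercept": -3.9,
        "age_per_10y": 0.25,
        "elixhauser": 0.06,
        "icu_lag2": 0.8,
        "creatinine_lag2": 0.25,
    },
    theta_discharge=1.0,
    signal_completeness=1.0,
    max_followup=90,
)

# smaller noisy cohort with a raised event rate for detector-level tests
DETECTOR_KW = dict(
    n_facilities=8,
    n_hospitalizations=1500,
    nvhap_onset_coefficients={
        "intercept": -4.5,
        "age_per_10y": 0.25,
        "elixhauser": 0.06,
        "icu_lag2": 0.8,
        "creatinine_lag2": 0.25,
    },
    max_followup=60,
)


def validation_config(seed: int, theta_death: float) -> SimConfig:
    return SimConfig(seed=seed, theta_death=theta_death, **VALIDATION_KW)


def merge_datasets(*datasets: Dataset) -> Dataset:
    """Concatenate single-admission fixtures into one dataset."""
    return Dataset(
        facilities=pd.concat([d.facilities for d in datasets]).drop_duplicates(
            "facility_id"
        ).reset_index(drop=True),
        hospitalizations=pd.concat(
            [d.hospitalizations for d in datasets], ignore_index=True
        ),
        daily=pd.concat([d.daily for d in datasets], ignore_index=True),
        medications=pd.concat([d.medications for d in datasets], ignore_index=True),
    )


def detect_one(ds: Dataset, params: SurveillanceParams | None = None):
    """Run the per-admission detector on a single-admission dataset."""
    params = params or SurveillanceParams()
    daily = impute_normal_oxygenation(ds.daily, params.spo2_normal)
    return detect_nvhap(ds.hospitalizations.iloc[0], daily, ds.medications, params)


def worked_detection_days() -> list[dict]:
    """Two stable room-air days, then deterioration with full supporting evidence."""
    return [
        dict(spo2=97),
        dict(spo2=97),
        dict(device="nasal_cannula", spo2=92, temp_max=38.6, imaging=True, agents=["pip_tazo"]),
        dict(device="nasal_cannula", spo2=92, agents=["pip_tazo"]),
        dict(agents=["pip_tazo"]),
        dict(),
    ]


@pytest.fixture()
def worked_fixture() -> Dataset:
    return plant_fixture(worked_detection_days())


@pytest.fixture(scope="session")
def detector_cohort():
    """Noisy cohort (signal completeness 0.9) with ground truth and detections."""
    cfg = SimConfig(seed=42, signal_completeness=0.9, **DETECTOR_KW)
    ds, truth = generate(cfg)
    events = detect_all(ds)
    return ds, truth, events


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Every true event carries its full signature; no background noise."""
    cfg = SimConfig(
        seed=7, signal_completeness=1.0, background_noise=0.0, **DETECTOR_KW
    )
    ds, truth = generate(cfg)
    events = detect_all(ds)
    return ds, truth, events


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on a confounded theta_death=1 cohort at n=20 000.

    Also computes the naive (unweighted censor-at-onset) contrast for the
    bias comparison.
    """
    cfg = validation_config(seed=11, theta_death=1.0)
    ds, truth = generate(cfg)
    events = detect_all(ds)
    est = estimate_attributable(ds, events)

    ids = eligible_cohort(ds)
    pdys = build_person_days(ds.subset(ids), events, horizon=60)
    curve_cur = weighted_aalen_johansen(pdys, 60)
    naive = pdys.copy()
    naive["weight"] = np.where(
        naive["onset_day"].isna() | (naive["t"] < naive["onset_day"]), 1.0, 0.0
    )
    curve_naive = weighted_aalen_johansen(naive, 60, weight_col="weight")
    naive_rr = float(curve_naive["cif_death"].iloc[-1] / curve_cur["cif_death"].iloc[-1])
    return {
        "config": cfg,
        "dataset": ds,
        "truth": truth,
        "events": events,
        "person_days": pdys,
        "estimate": est,
        "naive_rr": naive_rr,
    }
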