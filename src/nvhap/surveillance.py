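"""Electronic NV-HAP surveillance definition.

An admission meets the definition when all four criteria hold:

1. **Sustained oxygenation deterioration** — a decrease in oxygen saturation
   or an escalation of the oxygen-delivery device, sustained for 2 or more
   days, after 2 or more days of stable or improving oxygenation.
2. **Systemic sign** — abnormal temperature (<=36 °C or >=38 °C) or white
   blood cell count (<4.0 or >=12.0 x 10^3 cells/mm^3) near onset.
3. **Chest imaging** — an x-ray or CT completed near onset.
4. **New antimicrobials** — 3 or more consecutive days of antimicrobial
   administration starting on the first or second day of deterioration, with
   no antimicrobials in the preceding lookback window.

Events arising on a ventilator are out of scope (they are VAP): admissions
on a ventilator during both stable baseline days are excluded.  At most one
event is emitted per admission — the first qualifying onset day.

The daily oxygenation summary fed to the rule is the worst of the day
(minimum SpO2, highest-ranked device).  The SpO2 margin, criterion windows
and antimicrobial lookback are configurable; the defaults below are the
package's own choices where the published definition leaves them open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ehr_model import (
    Dataset,
    OXYGEN_DEVICES,
    VocabularyError,
    impute_normal_oxygenation,
)

_DEVICE_RANK = {name: i for i, name in enumerate(OXYGEN_DEVICES)}
VENTILATOR_RANK = _DEVICE_RANK["ventilator"]


@dataclass
class SurveillanceParams:
    """Tunable parameters of the surveillance definition."""

    spo2_drop: float = 3.0  # δ, percentage points of SpO2 counted as worsening
    temp_wbc_window: tuple[int, int] = (-2, 2)  # days relative to onset
    imaging_window: tuple[int, int] = (-1, 2)
    abx_lookback: int = 2  # antimicrobial-free days required before a "new" start
    abx_min_run: int = 3  # consecutive antimicrobial days required
    temp_low: float = 36.0  # inclusive
    temp_high: float = 38.0  # inclusive
    wbc_low: float = 4.0  # exclusive (<4.0 abnormal)
    wbc_high: float = 12.0  # inclusive (>=12.0 abnormal)
    spo2_normal: float = 97.0  # imputation value for missing oximetry


@dataclass(frozen=True)
class OxygenationState:
    """Worst-of-day oxygenation summary for one hospital day."""

    day: int
    device_rank: int
    spo2_min: float

    def __post_init__(self):
        if not 0 <= self.device_rank <= VENTILATOR_RANK:
            raise ValueError(f"device_rank {self.device_rank} outside 0..7")


@dataclass
class NVHAPEvent:
    """A detected surveillance event with criterion-level evidence."""

    hosp_id: str
    onset_day: int
    deterioration_days: tuple[int, int]
    temp_wbc_day: int
    temp_wbc_kind: str  # "temperature" or "wbc"
    temp_wbc_value: float
    imaging_day: int
    abx_start_day: int
    abx_days: tuple[int, ...]
    ventilated_at_baseline: bool = False


def rank_oxygen_device(device: Optional[str]) -> int:
    """Ordinal escalation rank of an oxygen-delivery device (none=0..ventilator=7).

    A missing device is treated as normal (rank 0).
    """
    if device is None or (isinstance(device, float) and np.isnan(device)):
        return 0
    try:
        return _DEVICE_RANK[device]
    except KeyError:
        raise VocabularyError(
            f"unknown oxygen device {device!r}; accepted: {', '.join(OXYGEN_DEVICES)}"
        ) from None


def _worse(rank_a: float, spo2_a: float, rank_b: float, spo2_b: float, delta: float) -> bool:
    """Is oxygenation on day a worse than on day b?"""
    return bool(rank_a > rank_b or spo2_a <= spo2_b - delta)


def detect_sustained_deterioration(
    states: Sequence[OxygenationState], delta: float
) -> list[int]:
    """Candidate onset days of sustained oxygenation deterioration.

    Day ``d`` is a candidate iff days ``d`` and ``d+1`` are each worse than
    the baseline day ``d-1`` (device rank strictly higher, or SpO2 at least
    ``delta`` points lower), and the two (or, at day 3, the one available)
    preceding day-over-day transitions are non-worsening, establishing >=2
    stable or improving days.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    days = [s.day for s in states]
    if days != list(range(1, len(states) + 1)):
        raise ValueError("states must cover contiguous days 1..los")
    rank = np.array([s.device_rank for s in states], dtype=float)
    spo2 = np.array([s.spo2_min for s in states], dtype=float)
    los = len(states)
    out = []
    for d in range(3, los):  # candidate day d needs day d+1 <= los
        b = d - 1  # baseline day
        w1 = _worse(rank[d - 1], spo2[d - 1], rank[b - 1], spo2[b - 1], delta)
        w2 = _worse(rank[d], spo2[d], rank[b - 1], spo2[b - 1], delta)
        stable1 = not _worse(rank[d - 2], spo2[d - 2], rank[d - 3], spo2[d - 3], delta)
        if d - 3 >= 1:
            stable2 = not _worse(
                rank[d - 3], spo2[d - 3], rank[d - 4], spo2[d - 4], delta
            )
        else:
            stable2 = True
        if w1 and w2 and stable1 and stable2:
            out.append(d)
    return out


def check_temp_wbc(
    daily: pd.DataFrame, onset_day: int, params: SurveillanceParams
) -> tuple[bool, Optional[dict]]:
    """Abnormal temperature or white-cell count within the onset window.

    Null measurements never satisfy the criterion.
    """
    lo, hi = params.temp_wbc_window
    sub = daily[(daily["day"] >= onset_day + lo) & (daily["day"] <= onset_day + hi)]
    sub = sub.sort_values("day")
    for _, row in sub.iterrows():
        t_min, t_max, wbc = row["temp_min"], row["temp_max"], row["wbc"]
        if pd.notna(t_min) and t_min <= params.temp_low:
            return True, {"day": int(row["day"]), "kind": "temperature", "value": float(t_min)}
        if pd.notna(t_max) and t_max >= params.temp_high:
            return True, {"day": int(row["day"]), "kind": "temperature", "value": float(t_max)}
        if pd.notna(wbc) and (wbc < params.wbc_low or wbc >= params.wbc_high):
            return True, {"day": int(row["day"]), "kind": "wbc", "value": float(wbc)}
    return False, None


def check_imaging(
    daily: pd.DataFrame, onset_day: int, params: SurveillanceParams
) -> tuple[bool, Optional[int]]:
    """Chest imaging completed within the onset window."""
    lo, hi = params.imaging_window
    sub = daily[
        (daily["day"] >= onset_day + lo)
        & (daily["day"] <= onset_day + hi)
        & daily["chest_imaging"].astype(bool)
    ]
    if len(sub):
        return True, int(sub["day"].min())
    return False, None


def check_new_antimicrobials(
    med_days: Iterable[int],
    onset_day: int,
    los: int,
    params: SurveillanceParams,
) -> tuple[bool, Optional[dict]]:
    """A >=``abx_min_run``-day new antimicrobial run starting on the first or
    second day of deterioration.

    "New" means no antimicrobial administration on the ``abx_lookback`` days
    before the start.  Agents may differ across days of the run.  A run
    truncated by discharge or death counts only if at least ``abx_min_run``
    days were observed.
    """
    days = set(int(d) for d in med_days)
    for start in (onset_day, onset_day + 1):
        if start + params.abx_min_run - 1 > los:
            continue  # truncated run, too short to qualify
        window = range(max(1, start - params.abx_lookback), start)
        if any(d in days for d in window):
            continue  # not new
        run = [start + k for k in range(params.abx_min_run)]
        if all(d in days for d in run):
            return True, {"start": start, "days": tuple(run)}
    return False, None


def _confirm(
    hosp_id: str,
    los: int,
    daily: pd.DataFrame,
    med_days: Iterable[int],
    rank: np.ndarray,
    candidates: Sequence[int],
    params: SurveillanceParams,
) -> Optional[NVHAPEvent]:
    """Check the conjunction of criteria at each candidate in order."""
    med_days = set(int(d) for d in med_days)
    for d in candidates:
        if rank[d - 3] >= VENTILATOR_RANK or rank[d - 2] >= VENTILATOR_RANK:
            continue  # ventilated at baseline: VAP, not NV-HAP
        ok_tw, ev_tw = check_temp_wbc(daily, d, params)
        if not ok_tw:
            continue
        ok_im, im_day = check_imaging(daily, d, params)
        if not ok_im:
            continue
        ok_abx, ev_abx = check_new_antimicrobials(med_days, d, los, params)
        if not ok_abx:
            continue
        return NVHAPEvent(
            hosp_id=hosp_id,
            onset_day=d,
            deterioration_days=(d, d + 1),
            temp_wbc_day=ev_tw["day"],
            temp_wbc_kind=ev_tw["kind"],
            temp_wbc_value=ev_tw["value"],
            imaging_day=im_day,
            abx_start_day=ev_abx["start"],
            abx_days=ev_abx["days"],
        )
    return None


def detect_nvhap(
    hosp: pd.Series | dict,
    daily: pd.DataFrame,
    medications: pd.DataFrame,
    params: SurveillanceParams | None = None,
) -> Optional[NVHAPEvent]:
    """Apply the full definition to a single admission.

    ``daily`` must already be imputed (no missing SpO2/device).  Returns the
    first qualifying event or ``None``.
    """
    params = params or SurveillanceParams()
    los = int(hosp["los"])
    daily = daily.sort_values("day")
    rank = daily["o2_device"].map(rank_oxygen_device).to_numpy(dtype=float)
    spo2 = daily["spo2_min"].to_numpy(dtype=float)
    states = [
        OxygenationState(day=i + 1, device_rank=int(rank[i]), spo2_min=spo2[i])
        for i in range(len(daily))
    ]
    candidates = detect_sustained_deterioration(states, params.spo2_drop)
    if not candidates:
        return None
    return _confirm(
        str(hosp["hosp_id"]), los, daily, medications["day"], rank, candidates, params
    )


def _candidate_mask(daily: pd.DataFrame, los_map: pd.Series, delta: float) -> pd.Series:
    """Vectorized candidate-onset mask over the full daily table.

    Equivalent to :func:`detect_sustained_deterioration` applied per
    admission (the equivalence is exercised against a brute-force oracle in
    the test suite).
    """
    df = daily.sort_values(["hosp_id", "day"])
    rank = df["_rank"]
    spo2 = df["spo2_min"]
    grp = df["hosp_id"]

    def shift(s: pd.Series, k: int) -> pd.Series:
        return s.groupby(grp, sort=False).shift(k)

    r1, r2, r3 = (shift(rank, k) for k in (1, 2, 3))
    s1, s2, s3 = (shift(spo2, k) for k in (1, 2, 3))
    rn, sn = shift(rank, -1), shift(spo2, -1)

    def worse(ra, sa, rb, sb):
        return (ra > rb) | (sa <= sb - delta)

    w_d = worse(rank, spo2, r1, s1)
    w_d1 = worse(rn, sn, r1, s1)
    stable1 = ~worse(r1, s1, r2, s2)
    stable2 = (~worse(r2, s2, r3, s3)) | r3.isna()
    day = df["day"]
    los = df["hosp_id"].map(los_map)
    mask = (
        (day >= 3)
        & (day + 1 <= los)
        & w_d.fillna(False)
        & w_d1.fillna(False)
        & stable1.fillna(False)
        & stable2.fillna(False)
    )
    return mask.reindex(daily.index)


def detect_all(
    dataset: Dataset, params: SurveillanceParams | None = None
) -> pd.DataFrame:
    """Run the definition across a dataset; one row per detected event.

    Candidate onset days are found with a vectorized pass over the daily
    table; only admissions with candidates are individually confirmed.
    """
    params = params or SurveillanceParams()
    daily = impute_normal_oxygenation(dataset.daily, params.spo2_normal)
    daily = daily.sort_values(["hosp_id", "day"]).reset_index(drop=True)
    daily["_rank"] = daily["o2_device"].map(rank_oxygen_device).astype(float)
    los_map = dataset.hospitalizations.set_index("hosp_id")["los"]

    if len(daily) == 0:
        return events_to_frame([])

    mask = _candidate_mask(daily, los_map, params.spo2_drop)
    cand = daily.loc[mask, ["hosp_id", "day"]]
    events: list[NVHAPEvent] = []
    if len(cand):
        meds_by_id = {
            hid: sub["day"].to_numpy()
            for hid, sub in dataset.medications.groupby("hosp_id", sort=False)
        }
        daily_by_id = dict(tuple(daily.groupby("hosp_id", sort=False)))
        for hid, sub in cand.groupby("hosp_id", sort=True):
            d_sub = daily_by_id[hid]
            ev = _confirm(
                str(hid),
                int(los_map[hid]),
                d_sub,
                meds_by_id.get(hid, ()),
                d_sub["_rank"].to_numpy(),
                sorted(int(d) for d in sub["day"]),
                params,
            )
            if ev is not None:
                events.append(ev)
    return events_to_frame(events)


EVENT_COLUMNS = [
    "hosp_id",
    "onset_day",
    "deterioration_day1",
    "deterioration_day2",
    "temp_wbc_day",
    "temp_wbc_kind",
    "temp_wbc_value",
    "imaging_day",
    "abx_start_day",
    "abx_days",
    "ventilated_at_baseline",
]


def events_to_frame(events: Sequence[NVHAPEvent]) -> pd.DataFrame:
    """Flatten detected events into the events.csv layout."""
    rows = [
        {
            "hosp_id": e.hosp_id,
            "onset_day": e.onset_day,
            "deterioration_day1": e.deterioration_days[0],
            "deterioration_day2": e.deterioration_days[1],
            "temp_wbc_day": e.temp_wbc_day,
            "temp_wbc_kind": e.temp_wbc_kind,
            "temp_wbc_value": e.temp_wbc_value,
            "imaging_day": e.imaging_day,
            "abx_start_day": e.abx_start_day,
            "abx_days": ";".join(str(d) for d in e.abx_days),
            "ventilated_at_baseline": e.ventilated_at_baseline,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(df) == 0:
        df = df.astype({"onset_day": int}, errors="ignore")
    return df
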