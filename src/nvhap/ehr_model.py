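"""Domain model and I/O for the three flat inpatient-EHR tables.

The analysis operates on four CSV tables:

``facilities.csv``
    one row per acute-care facility (bed-size class, teaching status, region);
``hospitalizations.csv``
    one row per admission (demographics, comorbidity flags, Elixhauser/van
    Walraven index, length of stay, discharge disposition);
``daily.csv``
    one row per hospitalization-day (service, ICU flag, vitals, pulse
    oximetry, oxygen-delivery device, routine and non-routine labs,
    chest-imaging flag);
``medications.csv``
    one row per hospitalization-day-antimicrobial.

Day indexing is 1-based calendar hospital day (admission day = 1); all
windows downstream are expressed in these units.  Dates are carried only on
the admission record.  Nullable numeric fields are empty CSV cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("nvhap")

# ---------------------------------------------------------------------------
# Closed category vocabularies
# ---------------------------------------------------------------------------

BED_SIZE_CLASSES = ["1-99", "100-199", "200-299", ">=300"]
REGIONS = ["Midwest", "Northeast", "South", "West"]
SEXES = ["female", "male"]
RACES = ["Asian", "Black", "White", "Other"]
DISPOSITIONS = ["home", "rehabilitation", "skilled_nursing", "hospice", "death", "other"]
ALIVE_DISPOSITIONS = [d for d in DISPOSITIONS if d != "death"]
SERVICES = ["cardiology", "medicine", "surgery", "neuroscience", "oncology", "other"]
COMORBIDITY_FLAGS = [
    "congestive_heart_failure",
    "chronic_lung_disease",
    "diabetes",
    "chronic_liver_disease",
    "cancer",
    "neurological_disease",
    "chronic_kidney_disease",
]

#: Oxygen-delivery devices in escalation order; list position is the ordinal
#: rank used by the deterioration rule (none=0 ... ventilator=7).
OXYGEN_DEVICES = [
    "none",
    "nasal_cannula",
    "simple_mask",
    "oxygen_conserving_device",
    "nonrebreather_mask",
    "high_flow_nasal_cannula",
    "bipap",
    "ventilator",
]

ROUTINE_LABS = ["wbc", "hematocrit", "platelets", "sodium", "glucose", "creatinine"]
NONROUTINE_LABS = ["alt", "bilirubin", "albumin"]

#: Default pulse-oximetry value imputed when a day has no recorded SpO2.
DEFAULT_SPO2_NORMAL = 97.0

# ---------------------------------------------------------------------------
# Schemas: column -> parse kind
# ---------------------------------------------------------------------------

FACILITY_SCHEMA: Mapping[str, str] = {
    "facility_id": "str",
    "bed_size_class": "str",
    "teaching": "bool",
    "region": "str",
}

HOSPITALIZATION_SCHEMA: Mapping[str, str] = {
    "hosp_id": "str",
    "facility_id": "str",
    "age": "int",
    "sex": "str",
    "race": "str",
    "admit_day": "str",
    "los": "int",
    "disposition": "str",
    **{flag: "bool" for flag in COMORBIDITY_FLAGS},
    "elixhauser_index": "int",
    "prior_90d_admission": "bool",
}

DAILY_SCHEMA: Mapping[str, str] = {
    "hosp_id": "str",
    "day": "int",
    "service": "str",
    "icu": "bool",
    "temp_min": "float",
    "temp_max": "float",
    "wbc": "float",
    "spo2_min": "float",
    "o2_device": "str?",
    "hematocrit": "float",
    "platelets": "float",
    "sodium": "float",
    "glucose": "float",
    "creatinine": "float",
    "alt": "float",
    "bilirubin": "float",
    "albumin": "float",
    "chest_imaging": "bool",
}

MEDICATION_SCHEMA: Mapping[str, str] = {
    "hosp_id": "str",
    "day": "int",
    "agent_id": "str",
}

TABLE_FILES = {
    "facilities": "facilities.csv",
    "hospitalizations": "hospitalizations.csv",
    "daily": "daily.csv",
    "medications": "medications.csv",
}

_SCHEMAS = {
    "facilities": FACILITY_SCHEMA,
    "hospitalizations": HOSPITALIZATION_SCHEMA,
    "daily": DAILY_SCHEMA,
    "medications": MEDICATION_SCHEMA,
}


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable column."""


class IntegrityError(ValueError):
    """Row-level invariants or referential integrity are violated."""


class VocabularyError(ValueError):
    """A categorical value is outside its closed vocabulary."""


@dataclass
class Dataset:
    """The four validated tables of one surveillance cohort."""

    facilities: pd.DataFrame
    hospitalizations: pd.DataFrame
    daily: pd.DataFrame
    medications: pd.DataFrame

    def subset(self, hosp_ids) -> "Dataset":
        """Restrict to the given admissions (facilities kept unchanged)."""
        ids = pd.Index(hosp_ids)
        return Dataset(
            facilities=self.facilities,
            hospitalizations=self.hospitalizations[
                self.hospitalizations["hosp_id"].isin(ids)
            ].reset_index(drop=True),
            daily=self.daily[self.daily["hosp_id"].isin(ids)].reset_index(drop=True),
            medications=self.medications[
                self.medications["hosp_id"].isin(ids)
            ].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_bool(series: pd.Series, table: str, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    s = series.astype("string").str.strip().str.lower()
    out = pd.Series(np.zeros(len(s), dtype=bool), index=series.index)
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        raise SchemaError(
            f"{table}.{col}: unparseable boolean value {s[bad].iloc[0]!r}"
        )
    out[s.isin(_TRUE)] = True
    return out


def _coerce(df: pd.DataFrame, schema: Mapping[str, str], table: str) -> pd.DataFrame:
    df = df.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        logger.warning("%s: ignoring unexpected column(s) %s", table, extra)
        df = df.drop(columns=extra)
    for col, kind in schema.items():
        try:
            if kind == "str":
                df[col] = df[col].astype("string").str.strip().astype(object)
            elif kind == "str?":
                s = df[col].astype("string").str.strip()
                df[col] = s.where(s.notna() & (s != ""), None).astype(object)
            elif kind == "int":
                df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
            elif kind == "float":
                df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
            elif kind == "bool":
                df[col] = _parse_bool(df[col], table, col)
        except SchemaError:
            raise
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{col}: {exc}") from exc
    return df[list(schema)]


def _check_domain(series: pd.Series, allowed, table: str, col: str) -> None:
    vals = series.dropna()
    bad = ~vals.isin(allowed)
    if bad.any():
        raise VocabularyError(
            f"{table}.{col}: value {vals[bad].iloc[0]!r} not in {sorted(allowed)}"
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(dataset: Dataset) -> Dataset:
    """Enforce schema invariants and referential integrity.

    Raises :class:`IntegrityError` / :class:`VocabularyError` on the first
    violation found; returns the dataset unchanged when clean.
    """
    fac, hosp, daily, meds = (
        dataset.facilities,
        dataset.hospitalizations,
        dataset.daily,
        dataset.medications,
    )

    if fac["facility_id"].duplicated().any():
        raise IntegrityError("facilities: duplicate facility_id")
    _check_domain(fac["bed_size_class"], BED_SIZE_CLASSES, "facilities", "bed_size_class")
    _check_domain(fac["region"], REGIONS, "facilities", "region")

    if hosp["hosp_id"].duplicated().any():
        raise IntegrityError("hospitalizations: duplicate hosp_id")
    _check_domain(hosp["sex"], SEXES, "hospitalizations", "sex")
    _check_domain(hosp["race"], RACES, "hospitalizations", "race")
    _check_domain(hosp["disposition"], DISPOSITIONS, "hospitalizations", "disposition")
    if (hosp["age"] < 18).any():
        raise IntegrityError("hospitalizations: age < 18")
    if (hosp["los"] < 1).any():
        raise IntegrityError("hospitalizations: los < 1")
    unknown_fac = ~hosp["facility_id"].isin(fac["facility_id"])
    if unknown_fac.any():
        raise IntegrityError(
            f"hospitalizations: unknown facility_id "
            f"{hosp.loc[unknown_fac, 'facility_id'].iloc[0]!r}"
        )

    los = hosp.set_index("hosp_id")["los"]
    for name, df in (("daily", daily), ("medications", meds)):
        unknown = ~df["hosp_id"].isin(los.index)
        if unknown.any():
            raise IntegrityError(
                f"{name}: unknown hosp_id {df.loc[unknown, 'hosp_id'].iloc[0]!r}"
            )
        day_los = df["hosp_id"].map(los)
        bad = (df["day"] < 1) | (df["day"] > day_los)
        if bad.any():
            row = df[bad].iloc[0]
            raise IntegrityError(
                f"{name}: day {row['day']} outside 1..los for {row['hosp_id']!r}"
            )

    if daily.duplicated(["hosp_id", "day"]).any():
        raise IntegrityError("daily: duplicate (hosp_id, day)")
    _check_domain(daily["service"], SERVICES, "daily", "service")
    dev = daily["o2_device"].dropna()
    _check_domain(dev, OXYGEN_DEVICES, "daily", "o2_device")

    # every hospitalization must have a contiguous 1..los day sequence
    counts = daily.groupby("hosp_id")["day"].count()
    counts = counts.reindex(los.index, fill_value=0)
    short = counts != los
    if short.any():
        hid = short[short].index[0]
        raise IntegrityError(
            f"daily: hospitalization {hid!r} has {counts[hid]} rows, expected los={los[hid]}"
        )

    if meds.duplicated(["hosp_id", "day", "agent_id"]).any():
        raise IntegrityError("medications: duplicate (hosp_id, day, agent_id)")

    logger.info(
        "validated dataset: %d facilities, %d hospitalizations, %d daily rows, %d medication rows",
        len(fac), len(hosp), len(daily), len(meds),
    )
    return dataset


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_tables(data_dir, *, validate_data: bool = True) -> Dataset:
    """Read the four CSV tables from ``data_dir`` and validate them.

    Column headers are matched case-insensitively against the schemas.
    """
    data_dir = Path(data_dir)
    frames = {}
    for key, fname in TABLE_FILES.items():
        path = data_dir / fname
        if not path.exists():
            raise FileNotFoundError(path)
        raw = pd.read_csv(path, dtype=str, keep_default_na=True)
        frames[key] = _coerce(raw, _SCHEMAS[key], key)
    ds = Dataset(**frames)
    return validate(ds) if validate_data else ds


def write_tables(dataset: Dataset, out_dir) -> None:
    """Write the four tables as CSV; nullable cells become empty strings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, fname in TABLE_FILES.items():
        df = getattr(dataset, key).copy()
        for col in df.columns:
            if df[col].dtype == bool:
                df[col] = df[col].astype(int)
        df.to_csv(out_dir / fname, index=False)


# ---------------------------------------------------------------------------
# Normal-oxygenation imputation
# ---------------------------------------------------------------------------

def impute_normal_oxygenation(
    daily: pd.DataFrame, spo2_normal: float = DEFAULT_SPO2_NORMAL
) -> pd.DataFrame:
    """Treat missing pulse oximetry / oxygen supplementation as normal.

    Missing ``spo2_min`` becomes ``spo2_normal`` (default 97%) and missing
    ``o2_device`` becomes ``"none"``; every other column, including other
    nullable labs, is left untouched.
    """
    out = daily.copy()
    out["spo2_min"] = out["spo2_min"].fillna(float(spo2_normal))
    out["o2_device"] = out["o2_device"].where(out["o2_device"].notna(), "none")
    return out
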