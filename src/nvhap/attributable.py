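"""Attributable inpatient mortality of NV-HAP under hypothetical elimination.

The estimand contrasts the cumulative incidence of inpatient death by a
60-day horizon (alive discharge is a competing risk) under **current care**
with the same quantity under **hypothetical elimination** of NV-HAP:

* a person-day file is built for eligible admissions (>=3 days, complete
  day-1/2 data) with covariates lagged 2 days (last observation carried
  forward);
* a pooled logistic propensity model estimates each at-risk person-day's
  probability of NV-HAP onset given baseline and lag-2 time-varying
  confounders, with a flexible (restricted cubic spline) day effect;
* under elimination, follow-up is censored at onset and the remaining
  event-free person-days are weighted by the inverse probability of having
  stayed event-free, W(t) = prod_{k=3..t} 1/(1 - p_hat(k));
* a weighted Aalen-Johansen estimator turns per-day cause-specific hazards
  into cumulative incidence functions F_death, F_discharge and survival S;
* the risk ratio (elimination / current care), risk difference and
  population attributable fraction (1 - risk ratio) are read off at the
  horizon, with percentile CIs from a clustered nonparametric bootstrap that
  resamples hospitalizations with replacement and refits the propensity
  model in every replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import ehr_model as em
from .ehr_model import Dataset, impute_normal_oxygenation
from .surveillance import rank_oxygen_device

logger = logging.getLogger("nvhap")

__all__ = [
    "CausalParams",
    "PositivityError",
    "AttributableEstimate",
    "eligible_cohort",
    "build_person_days",
    "fit_daily_propensity",
    "elimination_weights",
    "weighted_aalen_johansen",
    "estimate_attributable",
    "summarize_risks",
    "bootstrap_ci",
    "pool_sites",
    "stratified_estimates",
]


class PositivityError(RuntimeError):
    """A fitted per-day onset probability of 1 makes elimination weights undefined."""


@dataclass
class CausalParams:
    """Estimation settings for the elimination analysis."""

    horizon: int = 60  # days of follow-up
    day_effect: str = "spline"  # "spline" (restricted cubic) or "categorical"
    n_knots: int = 4
    truncation_quantile: float = 0.99  # upper quantile at which weights are capped
    stabilized: bool = False
    ridge_alpha: float = 1e-4  # L2 penalty used only as a separation fallback


# time-varying variables required complete on day 1 or 2 for cohort entry
ELIGIBILITY_VARS = ["service"] + em.ROUTINE_LABS

# lag-2 routine labs entering the propensity model (wbc is an eligibility
# variable but not a listed confounder)
_LAG_LABS = ["hematocrit", "platelets", "sodium", "glucose", "creatinine"]
_LAG_LAB_FALLBACK = {
    "hematocrit": 35.0,
    "platelets": 230.0,
    "sodium": 138.0,
    "glucose": 120.0,
    "creatinine": 1.0,
}

ALT_CATS = ["not_measured", "normal", "elevated", "high"]
BILI_CATS = ["not_measured", "normal", "elevated", "high"]
ALB_CATS = ["not_measured", "normal", "low", "very_low"]

_NUMERIC_COVARIATES = [
    "age_c",
    "elixhauser_index",
    "o2_rank",
    "spo2",
    "days_since_lab",
] + _LAG_LABS
_BOOL_COVARIATES = [
    "sex_female",
    "teaching",
    "prior_90d_admission",
    "icu",
] + em.COMORBIDITY_FLAGS
_CAT_COVARIATES = {
    "race": em.RACES,
    "bed_size_class": em.BED_SIZE_CLASSES,
    "region": em.REGIONS,
    "service": em.SERVICES,
    "alt_cat": ALT_CATS,
    "bilirubin_cat": BILI_CATS,
    "albumin_cat": ALB_CATS,
}


# ---------------------------------------------------------------------------
# cohort and person-day construction
# ---------------------------------------------------------------------------

def eligible_cohort(dataset: Dataset) -> np.ndarray:
    """Admissions entering the weighted analysis.

    Keeps hospitalizations of at least 3 days with a non-null value on day 1
    or day 2 for each of: hospital service, wbc, hematocrit, platelets,
    sodium, glucose, creatinine.
    """
    h = dataset.hospitalizations
    d12 = dataset.daily[dataset.daily["day"] <= 2]
    present = d12[ELIGIBILITY_VARS].notna()
    present.insert(0, "hosp_id", d12["hosp_id"].values)
    complete = present.groupby("hosp_id")[ELIGIBILITY_VARS].max().all(axis=1)
    ok_ids = complete[complete].index
    keep = h[(h["los"] >= 3) & h["hosp_id"].isin(ok_ids)]
    return np.sort(keep["hosp_id"].to_numpy())


def _nonroutine_category(values: pd.Series, var: str) -> pd.Series:
    v = values
    if var == "alt":
        out = np.select(
            [v.isna(), v <= 40, v <= 120], ["not_measured", "normal", "elevated"], "high"
        )
    elif var == "bilirubin":
        out = np.select(
            [v.isna(), v <= 1.2, v <= 2.5], ["not_measured", "normal", "elevated"], "high"
        )
    else:  # albumin: low values are the abnormal direction
        out = np.select(
            [v.isna(), v >= 3.5, v >= 2.8], ["not_measured", "normal", "low"], "very_low"
        )
    return pd.Series(out, index=values.index)


def build_person_days(
    dataset: Dataset, events: pd.DataFrame, horizon: int = 60
) -> pd.DataFrame:
    """One analysis row per hospitalization-day, t = 3..min(los, horizon).

    Time-varying covariates carry the most recent measured value at or
    before day ``t-2`` (LOCF); ``days_since_lab`` counts days from the
    current day ``t`` back to that last routine-lab day.  Outcome indicators
    sit on the terminal day; follow-up ends administratively at ``horizon``.
    """
    h = dataset.hospitalizations
    daily = impute_normal_oxygenation(dataset.daily)
    daily = daily.sort_values(["hosp_id", "day"]).reset_index(drop=True)
    daily["o2_rank"] = daily["o2_device"].map(rank_oxygen_device).astype(float)

    grp = daily.groupby("hosp_id", sort=False)
    lag_cols = _LAG_LABS + em.NONROUTINE_LABS
    ff = grp[lag_cols].ffill()
    routine_measured = daily[em.ROUTINE_LABS].notna().any(axis=1)
    lab_day = daily["day"].where(routine_measured)
    lab_day_ff = lab_day.groupby(daily["hosp_id"], sort=False).ffill()

    lagframe = pd.DataFrame(
        {
            "hosp_id": daily["hosp_id"],
            "lag_day": daily["day"],
            "service": daily["service"],
            "icu": daily["icu"],
            "o2_rank": daily["o2_rank"],
            "spo2": daily["spo2_min"],
            "lab_day": lab_day_ff,
            **{c: ff[c] for c in lag_cols},
        }
    )

    los = h["los"].clip(upper=horizon)
    n_rows = (los - 2).clip(lower=0)
    base = h.loc[n_rows > 0].reset_index(drop=True)
    counts = n_rows[n_rows > 0].to_numpy()
    rep = np.repeat(np.arange(len(base)), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    t = np.arange(counts.sum()) - np.repeat(offsets, counts) + 3

    pdys = pd.DataFrame({"hosp_id": base["hosp_id"].to_numpy()[rep], "t": t.astype(int)})
    pdys["lag_key"] = pdys["t"] - 2
    pdys = pdys.merge(
        lagframe,
        left_on=["hosp_id", "lag_key"],
        right_on=["hosp_id", "lag_day"],
        how="left",
        validate="many_to_one",
    ).drop(columns=["lag_key", "lag_day"])

    pdys["days_since_lab"] = (pdys["t"] - pdys["lab_day"]).fillna(pdys["t"]).astype(float)
    pdys = pdys.drop(columns=["lab_day"])
    for lab in _LAG_LABS:
        med = pdys[lab].median()
        if np.isnan(med):
            med = _LAG_LAB_FALLBACK[lab]
        pdys[lab] = pdys[lab].fillna(med)
    for lab in em.NONROUTINE_LABS:
        cat = "alt_cat" if lab == "alt" else f"{lab}_cat"
        pdys[cat] = _nonroutine_category(pdys[lab], lab)
    pdys = pdys.drop(columns=em.NONROUTINE_LABS)

    base_cols = [
        "hosp_id",
        "facility_id",
        "age",
        "sex",
        "race",
        "los",
        "disposition",
        "elixhauser_index",
        "prior_90d_admission",
    ] + em.COMORBIDITY_FLAGS
    pdys = pdys.merge(h[base_cols], on="hosp_id", how="left")
    pdys = pdys.merge(dataset.facilities, on="facility_id", how="left")
    pdys["age_c"] = (pdys["age"] - 65.0) / 10.0
    pdys["sex_female"] = pdys["sex"] == "female"

    onset = events.set_index("hosp_id")["onset_day"] if len(events) else pd.Series(dtype=float)
    pdys["onset_day"] = pdys["hosp_id"].map(onset).astype(float)
    if (pdys["onset_day"] < 3).any():
        raise em.IntegrityError("event onset before day 3")
    pdys["nvhap_onset_today"] = pdys["t"] == pdys["onset_day"]
    pdys["at_risk"] = pdys["onset_day"].isna() | (pdys["t"] <= pdys["onset_day"])

    terminal = (pdys["t"] == pdys["los"]) & (pdys["los"] <= horizon)
    pdys["death_today"] = terminal & (pdys["disposition"] == "death")
    pdys["discharge_today"] = terminal & (pdys["disposition"] != "death")
    return pdys.sort_values(["hosp_id", "t"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), k knots -> k-1 columns."""
    k = len(knots)
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            pos3(x - knots[j])
            - pos3(x - knots[-2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + pos3(x - knots[-1]) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class _DesignSpec:
    day_effect: str
    knots: Optional[np.ndarray]
    day_levels: Optional[np.ndarray]
    numeric: list
    bools: list
    cats: Mapping[str, Sequence[str]]
    scaling: dict
    columns: Optional[list] = None


def _build_design(df: pd.DataFrame, spec: _DesignSpec) -> pd.DataFrame:
    parts = {"intercept": np.ones(len(df))}
    t = df["t"].to_numpy(dtype=float)
    if spec.day_effect == "spline":
        basis = _rcs_basis(t, spec.knots)
        for i in range(basis.shape[1]):
            parts[f"day_rcs{i}"] = basis[:, i]
    elif spec.day_effect == "categorical":
        for lev in spec.day_levels[1:]:
            parts[f"day_{int(lev)}"] = (t == lev).astype(float)
    else:
        raise ValueError(f"unknown day_effect {spec.day_effect!r}")
    for col in spec.numeric:
        mean, sd = spec.scaling[col]
        parts[col] = (df[col].to_numpy(dtype=float) - mean) / sd
    for col in spec.bools:
        parts[col] = df[col].to_numpy(dtype=float)
    for col, levels in spec.cats.items():
        vals = df[col]
        for lev in levels[1:]:
            parts[f"{col}_{lev}"] = (vals == lev).to_numpy(dtype=float)
    X = pd.DataFrame(parts, index=df.index)
    if spec.columns is not None:
        X = X[spec.columns]
    return X


@dataclass
class PropensityModel:
    """Fitted pooled logistic model for the daily NV-HAP onset hazard."""

    spec: Optional[_DesignSpec]
    params: Optional[pd.Series]
    trivial: bool = False  # no onsets at all: p_hat identically 0
    ridged: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.trivial:
            return np.zeros(len(df))
        X = _build_design(df, self.spec)
        return expit(X.to_numpy(dtype=float) @ self.params.to_numpy())


def fit_daily_propensity(
    person_days: pd.DataFrame,
    params: CausalParams | None = None,
    covariates: Optional[Sequence[str]] = None,
) -> PropensityModel:
    """Fit the pooled per-day onset model on at-risk, event-free-through-t-1 rows.

    ``covariates=None`` uses the full default confounder set; an explicit
    list restricts the model to those (numeric) columns; ``[]`` fits the
    day effect alone — with a categorical day effect and no covariates the
    fitted probability equals the empirical onset hazard of each day.
    """
    params = params or CausalParams()
    fit_df = person_days[person_days["at_risk"]]
    y = fit_df["nvhap_onset_today"].to_numpy(dtype=float)
    if y.sum() == 0:
        return PropensityModel(spec=None, params=None, trivial=True)

    if covariates is None:
        numeric, bools, cats = list(_NUMERIC_COVARIATES), list(_BOOL_COVARIATES), dict(_CAT_COVARIATES)
    else:
        numeric, bools, cats = list(covariates), [], {}

    t = fit_df["t"].to_numpy(dtype=float)
    if params.day_effect == "spline":
        qs = np.linspace(0.05, 0.95, params.n_knots)
        knots = np.unique(np.quantile(t, qs))
        if len(knots) < 3:  # degenerate day range: fall back to linear day
            knots = None
        day_levels = None
    else:
        knots = None
        day_levels = np.unique(t)
    spec = _DesignSpec(
        day_effect=params.day_effect if knots is not None or params.day_effect == "categorical" else "categorical",
        knots=knots,
        day_levels=day_levels if day_levels is not None else np.unique(t),
        numeric=numeric,
        bools=bools,
        cats=cats,
        scaling={},
    )
    for col in numeric:
        v = fit_df[col].to_numpy(dtype=float)
        sd = v.std()
        spec.scaling[col] = (float(v.mean()), float(sd) if sd > 1e-8 else 1.0)

    X = _build_design(fit_df, spec)
    keep = ["intercept"] + [
        c for c in X.columns if c != "intercept" and X[c].std() > 1e-12
    ]
    spec.columns = keep
    X = X[keep]

    glm = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial())
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=200)
        beta = np.asarray(res.params)
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e3:
            raise ValueError("diverged")
    except Exception:  # separation or non-convergence: weak ridge fallback
        warnings.warn(
            "propensity fit did not converge cleanly; refitting with a weak L2 penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        res = glm.fit_regularized(alpha=params.ridge_alpha, L1_wt=0.0)
        beta = np.asarray(res.params)
        ridged = True

    return PropensityModel(
        spec=spec, params=pd.Series(beta, index=keep), ridged=ridged
    )


# ---------------------------------------------------------------------------
# weights and the weighted Aalen-Johansen estimator
# ---------------------------------------------------------------------------

def elimination_weights(
    person_days: pd.DataFrame,
    model: PropensityModel,
    truncation_quantile: float = 0.99,
    stabilized: bool = False,
    cluster_col: str = "hosp_id",
) -> pd.DataFrame:
    """Inverse-probability weights for the elimination scenario.

    Follow-up is censored at NV-HAP onset (the onset day and everything
    after get weight 0); an event-free row at day t gets
    W(t) = prod_{k<=t} 1/(1 - p_hat(k)) over its at-risk days, optionally
    stabilized by the marginal event-free probability, then truncated at the
    configured upper quantile.
    """
    df = person_days.sort_values([cluster_col, "t"]).reset_index(drop=True)
    at = df["at_risk"].to_numpy(dtype=bool)
    p = np.zeros(len(df))
    if at.any():
        p[at] = model.predict(df[at])
    if np.any(p >= 1.0 - 1e-12):
        raise PositivityError("fitted onset probability of 1 on some person-day")

    factor = np.where(at, 1.0 / (1.0 - p), 1.0)
    cum = pd.Series(factor).groupby(df[cluster_col], sort=False).cumprod().to_numpy()
    if stabilized:
        pbar = pd.Series(np.where(at, p, np.nan)).groupby(df["t"]).transform("mean")
        num_factor = np.where(at, 1.0 - pbar.to_numpy(), 1.0)
        num = pd.Series(num_factor).groupby(df[cluster_col], sort=False).cumprod().to_numpy()
        cum = cum * num

    free = df["onset_day"].isna() | (df["t"] < df["onset_day"])
    w = np.where(free.to_numpy(), cum, 0.0)
    positive = w[w > 0]
    if len(positive):
        cap = np.quantile(positive, truncation_quantile)
        w = np.minimum(w, cap)
    df["weight"] = w
    return df


def weighted_aalen_johansen(
    person_days: pd.DataFrame, horizon: int, weight_col: Optional[str] = None
) -> pd.DataFrame:
    """Weighted Aalen-Johansen cumulative incidence of death and discharge.

    Per day t: lambda_e(t) = sum_i W_i(t) I(event e at t) / sum_i W_i(t) over
    rows present at t; S(t) = prod(1 - lambda_death - lambda_discharge);
    F_e(t) = sum_{s<=t} lambda_e(s) S(s-1).  Days without at-risk mass get
    zero hazards (flat curve).
    """
    df = person_days
    w = df[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(df))
    keep = (w > 0) & (df["t"].to_numpy() <= horizon)
    sub = df[keep]
    w = w[keep]
    if len(sub) == 0:
        days = np.arange(3, horizon + 1)
        zero = np.zeros(len(days))
        return pd.DataFrame(
            {"day": days, "lam_death": zero, "lam_discharge": zero,
             "surv": np.ones(len(days)), "cif_death": zero, "cif_discharge": zero}
        )

    t = sub["t"].to_numpy()
    death = sub["death_today"].to_numpy(dtype=float)
    disc = sub["discharge_today"].to_numpy(dtype=float)
    agg = pd.DataFrame({"t": t, "denom": w, "death": w * death, "disc": w * disc})
    agg = agg.groupby("t").sum()

    days = np.arange(int(agg.index.min()), horizon + 1)
    agg = agg.reindex(days, fill_value=0.0)
    denom = agg["denom"].to_numpy()
    empty = denom <= 0
    if empty.any():
        logger.debug("no at-risk mass on %d day(s); hazards set to 0", int(empty.sum()))
    safe = np.where(empty, 1.0, denom)
    lam_d = np.where(empty, 0.0, agg["death"].to_numpy() / safe)
    lam_c = np.where(empty, 0.0, agg["disc"].to_numpy() / safe)

    surv = np.cumprod(1.0 - lam_d - lam_c)
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    cif_d = np.cumsum(lam_d * surv_prev)
    cif_c = np.cumsum(lam_c * surv_prev)
    return pd.DataFrame(
        {
            "day": days,
            "lam_death": lam_d,
            "lam_discharge": lam_c,
            "surv": surv,
            "cif_death": cif_d,
            "cif_discharge": cif_c,
        }
    )


# ---------------------------------------------------------------------------
# the contrast
# ---------------------------------------------------------------------------

def summarize_risks(risk_current: float, risk_eliminated: float) -> dict:
    """Risk difference, risk ratio (elimination vs current care) and
    attributable fraction 1 - RR, from two risks on the percent scale."""
    rr = risk_eliminated / risk_current if risk_current > 0 else np.nan
    return {
        "risk_difference": risk_current - risk_eliminated,
        "risk_ratio": rr,
        "attributable_fraction": 1.0 - rr,
    }


@dataclass
class AttributableEstimate:
    """Cumulative-incidence contrast at the horizon (risks in percent)."""

    horizon: int
    risk_current: float
    risk_eliminated: float
    risk_difference: float
    risk_ratio: float
    attributable_fraction: float
    n_hospitalizations: int
    n_events: int
    curve_current: Optional[pd.DataFrame] = None
    curve_eliminated: Optional[pd.DataFrame] = None
    ci: Optional[dict] = None
    replicates: Optional[pd.DataFrame] = None

    _FIELDS = (
        "risk_current",
        "risk_eliminated",
        "risk_difference",
        "risk_ratio",
        "attributable_fraction",
    )

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self._FIELDS}
        out.update(
            horizon=self.horizon,
            n_hospitalizations=self.n_hospitalizations,
            n_events=self.n_events,
        )
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def _estimate_from_person_days(
    pdys: pd.DataFrame,
    params: CausalParams,
    cluster_col: str = "hosp_id",
    keep_curves: bool = True,
) -> AttributableEstimate:
    curve_cur = weighted_aalen_johansen(pdys, params.horizon)
    model = fit_daily_propensity(pdys, params)
    weighted = elimination_weights(
        pdys, model, params.truncation_quantile, params.stabilized, cluster_col
    )
    curve_elim = weighted_aalen_johansen(weighted, params.horizon, weight_col="weight")

    risk_cur = float(curve_cur["cif_death"].iloc[-1]) * 100.0
    risk_elim = float(curve_elim["cif_death"].iloc[-1]) * 100.0
    summary = summarize_risks(risk_cur, risk_elim)
    return AttributableEstimate(
        horizon=params.horizon,
        risk_current=risk_cur,
        risk_eliminated=risk_elim,
        n_hospitalizations=int(pdys[cluster_col].nunique()),
        n_events=int(pdys["nvhap_onset_today"].sum()),
        curve_current=curve_cur if keep_curves else None,
        curve_eliminated=curve_elim if keep_curves else None,
        **summary,
    )


def estimate_attributable(
    dataset: Dataset, events: pd.DataFrame, params: CausalParams | None = None
) -> AttributableEstimate:
    """Point estimate of the elimination contrast on one dataset."""
    params = params or CausalParams()
    ids = eligible_cohort(dataset)
    if len(ids) == 0:
        raise ValueError("no eligible hospitalizations")
    pdys = build_person_days(dataset.subset(ids), events, horizon=params.horizon)
    return _estimate_from_person_days(pdys, params)


def bootstrap_ci(
    dataset: Dataset,
    events: pd.DataFrame,
    params: CausalParams | None = None,
    B: int = 500,
    seed: int = 0,
) -> AttributableEstimate:
    """Clustered nonparametric bootstrap: resample hospitalizations with
    replacement, re-run the full pipeline (including the propensity refit)
    per replicate, and take percentile 2.5/97.5 intervals.

    Deterministic given ``seed``.  Replicates with zero events are recorded
    with risk ratio 1 and flagged.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    params = params or CausalParams()
    ids = eligible_cohort(dataset)
    if len(ids) == 0:
        raise ValueError("no eligible hospitalizations")
    pdys = build_person_days(dataset.subset(ids), events, horizon=params.horizon)
    point = _estimate_from_person_days(pdys, params)

    groups = pdys.groupby("hosp_id", sort=True).indices
    uids = list(groups)
    row_idx = [np.asarray(groups[u]) for u in uids]
    sizes = np.array([len(r) for r in row_idx])
    m = len(uids)

    rng = np.random.default_rng(seed)
    rows_out = []
    for b in range(B):
        pick = rng.integers(0, m, m)
        rows = np.concatenate([row_idx[i] for i in pick])
        rep = pdys.iloc[rows].reset_index(drop=True)
        rep["_cluster"] = np.repeat(np.arange(m), sizes[pick])
        flagged = False
        if rep["nvhap_onset_today"].sum() == 0:
            curve = weighted_aalen_johansen(rep, params.horizon)
            risk = float(curve["cif_death"].iloc[-1]) * 100.0
            est = {
                "risk_current": risk,
                "risk_eliminated": risk,
                "risk_difference": 0.0,
                "risk_ratio": 1.0,
                "attributable_fraction": 0.0,
            }
            flagged = True
        else:
            rep_est = _estimate_from_person_days(
                rep, params, cluster_col="_cluster", keep_curves=False
            )
            est = {k: getattr(rep_est, k) for k in AttributableEstimate._FIELDS}
        est["flagged_zero_events"] = flagged
        rows_out.append(est)

    reps = pd.DataFrame(rows_out)
    ci = {
        k: (
            float(np.percentile(reps[k], 2.5)),
            float(np.percentile(reps[k], 97.5)),
        )
        for k in AttributableEstimate._FIELDS
    }
    point.ci = ci
    point.replicates = reps
    return point


def pool_sites(
    estimates: Sequence[AttributableEstimate], sizes: Sequence[float]
) -> AttributableEstimate:
    """Pool site-level estimates with weights proportional to sample size.

    Point estimates and (when present) bootstrap replicates are pooled as
    weighted averages; intervals are percentiles of the pooled replicates.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one site")
    if len(estimates) != len(sizes):
        raise ValueError("one size per site required")
    w = np.asarray(sizes, dtype=float)
    w = w / w.sum()

    vals = {
        k: float(np.sum(w * np.array([getattr(e, k) for e in estimates])))
        for k in AttributableEstimate._FIELDS
    }
    horizon = estimates[0].horizon
    pooled = AttributableEstimate(
        horizon=horizon,
        n_hospitalizations=int(sum(e.n_hospitalizations for e in estimates)),
        n_events=int(sum(e.n_events for e in estimates)),
        **vals,
    )
    reps = [e.replicates for e in estimates]
    if all(r is not None for r in reps):
        lengths = {len(r) for r in reps}
        if len(lengths) != 1:
            raise ValueError("mismatched replicate counts across sites")
        pooled_reps = sum(
            wi * r[list(AttributableEstimate._FIELDS)].reset_index(drop=True)
            for wi, r in zip(w, reps)
        )
        pooled.replicates = pooled_reps
        pooled.ci = {
            k: (
                float(np.percentile(pooled_reps[k], 2.5)),
                float(np.percentile(pooled_reps[k], 97.5)),
            )
            for k in AttributableEstimate._FIELDS
        }
    return pooled


def stratified_estimates(
    dataset: Dataset,
    events: pd.DataFrame,
    strata_spec,
    params: CausalParams | None = None,
) -> dict:
    """Re-run the elimination contrast within strata of the admissions.

    ``strata_spec`` may be ``"all"`` (single stratum), a column name of the
    hospitalizations table, or a callable mapping the hospitalizations frame
    to a label per admission.  Strata where the pipeline cannot run are
    reported as ``None`` rather than aborting the whole analysis.
    """
    params = params or CausalParams()
    h = dataset.hospitalizations
    if strata_spec == "all" or strata_spec is None:
        labels = pd.Series("all", index=h.index)
    elif callable(strata_spec):
        labels = pd.Series(strata_spec(h), index=h.index)
    elif isinstance(strata_spec, str):
        labels = h[strata_spec]
    else:
        raise TypeError("strata_spec must be 'all', a column name, or a callable")

    out: dict = {}
    for label in sorted(labels.dropna().unique()):
        ids = h.loc[labels == label, "hosp_id"]
        sub = dataset.subset(ids)
        try:
            out[str(label)] = estimate_attributable(sub, events, params)
        except (ValueError, PositivityError) as exc:
            logger.warning("stratum %r not estimable: %s", label, exc)
            out[str(label)] = None
    return out
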