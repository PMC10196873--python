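"""Estimator tests: eligibility, person-day construction, propensity model,
IP weights, weighted Aalen-Johansen (hand fixture, brute-force oracle,
Kaplan-Meier collapse), pooling, strata, and bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest

from nvhap import (
    CausalParams,
    bootstrap_ci,
    build_person_days,
    detect_all,
    eligible_cohort,
    elimination_weights,
    estimate_attributable,
    fit_daily_propensity,
    pool_sites,
    plant_fixture,
    stratified_estimates,
    summarize_risks,
    weighted_aalen_johansen,
)
from nvhap.attributable import AttributableEstimate

from conftest import merge_datasets, worked_detection_days

EMPTY_EVENTS = pd.DataFrame(columns=["hosp_id", "onset_day"])


# ---------------------------------------------------------------------------
# eligibility and person-days
# ---------------------------------------------------------------------------

class TestEligibility:
    def test_short_stays_excluded(self):
        ds = plant_fixture([dict(), dict()], hosp_id="H1")
        assert len(eligible_cohort(ds)) == 0

    def test_missing_routine_lab_on_both_early_days_excluded(self):
        days = [dict(creatinine=None)] * 5
        ds = plant_fixture(days, hosp_id="H1")
        assert len(eligible_cohort(ds)) == 0

    def test_complete_day1_data_included(self):
        ds = plant_fixture([dict(), dict(), dict()], hosp_id="H1")
        assert list(eligible_cohort(ds)) == ["H1"]

    def test_day2_measurement_suffices(self):
        days = [dict(sodium=None), dict(), dict()]
        ds = plant_fixture(days, hosp_id="H1")
        assert list(eligible_cohort(ds)) == ["H1"]


class TestPersonDays:
    def test_row_range_is_3_to_los(self):
        ds = plant_fixture([dict()] * 4)
        pdys = build_person_days(ds, EMPTY_EVENTS)
        assert pdys["t"].tolist() == [3, 4]

    def test_locf_lag2_and_days_since_lab(self):
        # creatinine (and the whole routine panel) measured on day 1 only
        blank = dict(
            wbc=None, hematocrit=None, platelets=None,
            sodium=None, glucose=None, creatinine=None,
        )
        days = [dict(creatinine=1.7)] + [dict(blank) for _ in range(5)]
        ds = plant_fixture(days)
        pdys = build_person_days(ds, EMPTY_EVENTS)
        row = pdys[pdys["t"] == 5].iloc[0]
        assert row["creatinine"] == 1.7  # day-1 value carried forward to lag day 3
        assert row["days_since_lab"] == 4  # measured 4 days before day 5

    def test_death_after_horizon_is_censored(self):
        ds = plant_fixture([dict()] * 70, disposition="death")
        pdys = build_person_days(ds, EMPTY_EVENTS, horizon=60)
        assert pdys["t"].max() == 60
        assert not pdys["death_today"].any()
        assert not pdys["discharge_today"].any()

    def test_outcome_sits_on_terminal_day(self):
        ds = plant_fixture([dict()] * 5, disposition="death")
        pdys = build_person_days(ds, EMPTY_EVENTS)
        assert pdys.loc[pdys["t"] == 5, "death_today"].item()
        assert pdys["death_today"].sum() == 1

    def test_hospice_counts_as_alive_discharge(self):
        ds = plant_fixture([dict()] * 4, disposition="hospice")
        pdys = build_person_days(ds, EMPTY_EVENTS)
        assert pdys.loc[pdys["t"] == 4, "discharge_today"].item()

    def test_at_risk_and_onset_flags(self):
        ds = plant_fixture([dict()] * 6)
        events = pd.DataFrame({"hosp_id": ["H000001"], "onset_day": [4]})
        pdys = build_person_days(ds, events)
        assert pdys.set_index("t")["at_risk"].tolist() == [True, True, False, False]
        assert pdys.loc[pdys["t"] == 4, "nvhap_onset_today"].item()


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

def _person_day_frame(t, y, **covs):
    df = pd.DataFrame({"hosp_id": [f"H{i}" for i in range(len(t))], "t": t})
    df["at_risk"] = True
    df["nvhap_onset_today"] = np.asarray(y, dtype=bool)
    df["onset_day"] = np.where(df["nvhap_onset_today"], df["t"], np.nan)
    for k, v in covs.items():
        df[k] = v
    return df


def test_saturated_day_model_equals_empirical_hazard():
    t = np.array([3] * 100 + [4] * 50)
    y = np.zeros(150, dtype=bool)
    y[:2] = True  # 2 of 100 onsets on day 3
    y[100] = True  # 1 of 50 on day 4
    df = _person_day_frame(t, y)
    model = fit_daily_propensity(df, CausalParams(day_effect="categorical"), covariates=[])
    p = model.predict(df)
    assert np.allclose(p[t == 3], 0.02, atol=1e-6)
    assert np.allclose(p[t == 4], 0.02, atol=1e-6)


def test_zero_onsets_give_trivial_model_and_unit_weights():
    df = _person_day_frame(np.repeat([3, 4, 5], 30), np.zeros(90, dtype=bool))
    model = fit_daily_propensity(df, covariates=[])
    assert model.trivial
    w = elimination_weights(df, model)["weight"]
    assert np.allclose(w, 1.0)


def test_coefficient_recovery_from_known_logistic_model():
    """Person-days simulated from a known onset model; the pooled fit must
    recover the coefficients (tolerance ~2.5 analytic SEs at this size)."""
    rng = np.random.default_rng(3)
    n_subj, t_max = 6000, 10
    rows = []
    for i in range(n_subj):
        x1 = rng.normal()
        for t in range(3, t_max + 1):
            x2 = rng.normal()
            p = 1 / (1 + np.exp(-(-4.0 + 0.5 * x1 - 0.3 * x2 + 0.05 * (t - 3))))
            y = rng.random() < p
            rows.append((f"H{i}", t, y, x1, x2))
            if y:
                break
    df = pd.DataFrame(rows, columns=["hosp_id", "t", "nvhap_onset_today", "x1", "x2"])
    df["at_risk"] = True
    df["onset_day"] = np.where(df["nvhap_onset_today"], df["t"], np.nan)
    model = fit_daily_propensity(df, CausalParams(day_effect="spline"), covariates=["x1", "x2"])
    for name, truth in (("x1", 0.5), ("x2", -0.3)):
        sd = model.spec.scaling[name][1]
        beta = model.params[name] / sd  # undo the internal standardization
        assert beta == pytest.approx(truth, abs=0.1)


# ---------------------------------------------------------------------------
# elimination weights
# ---------------------------------------------------------------------------

class _FixedP:
    """Stand-in propensity model with prescribed per-day probabilities."""

    trivial = False

    def __init__(self, p_by_day):
        self.p_by_day = p_by_day

    def predict(self, df):
        return df["t"].map(self.p_by_day).to_numpy(dtype=float)


def test_weight_hand_computation():
    df = _person_day_frame([3, 4, 5], [False, False, False])
    df["hosp_id"] = "H1"
    out = elimination_weights(df, _FixedP({3: 0.1, 4: 0.2, 5: 0.0}),
                              truncation_quantile=1.0)
    expected = [1 / 0.9, 1 / 0.9 / 0.8, 1 / 0.9 / 0.8]
    assert np.allclose(out.sort_values("t")["weight"], expected)


def test_onset_day_and_after_get_zero_weight():
    df = _person_day_frame([3, 4, 5], [False, False, False])
    df["hosp_id"] = "H1"
    df["onset_day"] = 4.0
    df["at_risk"] = df["t"] <= 4
    df["nvhap_onset_today"] = df["t"] == 4
    out = elimination_weights(df, _FixedP({3: 0.1, 4: 0.1, 5: 0.1}))
    out = out.sort_values("t")
    assert out["weight"].iloc[0] > 0
    assert (out["weight"].iloc[1:] == 0).all()


def test_positivity_violation_aborts():
    df = _person_day_frame([3], [False])
    with pytest.raises(Exception, match="[Pp]ositivity|probability"):
        elimination_weights(df, _FixedP({3: 1.0}))


def test_mean_weight_matches_inverse_event_free_probability():
    """IPW identity: with a constant hazard p, the (common) weight at day t
    equals 1/P(event-free through t) = (1-p)^-(t-2)."""
    rng = np.random.default_rng(8)
    p_true, t_max = 0.05, 10
    rows = []
    for i in range(4000):
        for t in range(3, t_max + 1):
            y = rng.random() < p_true
            rows.append((f"H{i}", t, y))
            if y:
                break
    df = pd.DataFrame(rows, columns=["hosp_id", "t", "nvhap_onset_today"])
    df["at_risk"] = True
    df["onset_day"] = np.where(df["nvhap_onset_today"], df["t"], np.nan)
    model = fit_daily_propensity(df, CausalParams(day_effect="categorical"), covariates=[])
    out = elimination_weights(df, model, truncation_quantile=1.0)
    free = out[out["weight"] > 0]
    for t in (5, 10):
        mean_w = free.loc[free["t"] == t, "weight"].mean()
        assert mean_w == pytest.approx((1 - p_true) ** -(t - 2), rel=0.1)


# ---------------------------------------------------------------------------
# weighted Aalen-Johansen
# ---------------------------------------------------------------------------

def aj_rows(subjects):
    """subjects: list of (duration, cause) with cause in {death, discharge, None}."""
    rows = []
    for i, (dur, cause) in enumerate(subjects):
        for t in range(1, dur + 1):
            rows.append(
                {
                    "hosp_id": f"S{i}",
                    "t": t,
                    "death_today": cause == "death" and t == dur,
                    "discharge_today": cause == "discharge" and t == dur,
                }
            )
    return pd.DataFrame(rows)


def test_hand_computed_four_subject_fixture():
    df = aj_rows([(1, "death"), (2, "discharge"), (3, "death"), (3, None)])
    curve = weighted_aalen_johansen(df, horizon=3)
    at3 = curve[curve["day"] == 3].iloc[0]
    assert at3["cif_death"] == pytest.approx(0.5, abs=1e-12)
    assert at3["cif_discharge"] == pytest.approx(0.25, abs=1e-12)
    assert at3["surv"] == pytest.approx(0.25, abs=1e-12)


def oracle_aj(df, horizon, weights=None):
    """Independent day-by-day tabulation with plain Python loops."""
    w = weights if weights is not None else pd.Series(1.0, index=df.index)
    days = sorted(d for d in df["t"].unique() if d <= horizon)
    s, fd, fc = 1.0, 0.0, 0.0
    out = {}
    for d in range(days[0], horizon + 1):
        denom = dth = dis = 0.0
        for i in df.index[df["t"] == d]:
            if w[i] > 0:
                denom += w[i]
                dth += w[i] * bool(df.at[i, "death_today"])
                dis += w[i] * bool(df.at[i, "discharge_today"])
        ld = dth / denom if denom > 0 else 0.0
        lc = dis / denom if denom > 0 else 0.0
        fd += ld * s
        fc += lc * s
        s *= 1 - ld - lc
        out[d] = (fd, fc, s)
    return out


def test_estimator_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(12)
    for trial in range(1000):
        n = rng.integers(1, 21)
        subjects = [
            (int(rng.integers(1, 9)), ["death", "discharge", None][rng.integers(3)])
            for _ in range(n)
        ]
        df = aj_rows(subjects)
        w = pd.Series(rng.uniform(0.0, 3.0, len(df)), index=df.index)
        df["weight"] = w
        horizon = int(rng.integers(3, 12))
        curve = weighted_aalen_johansen(df, horizon, weight_col="weight")
        expected = oracle_aj(df[w > 0], horizon, w[w > 0])
        for _, row in curve.iterrows():
            fd, fc, s = expected[row["day"]]
            assert abs(row["cif_death"] - fd) < 1e-12
            assert abs(row["cif_discharge"] - fc) < 1e-12
            assert abs(row["surv"] - s) < 1e-12


def test_single_event_type_collapses_to_kaplan_meier():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(4)
    durations = rng.integers(1, 15, 200)
    observed = rng.random(200) < 0.7
    df = aj_rows(
        [(int(d), "death" if o else None) for d, o in zip(durations, observed)]
    )
    curve = weighted_aalen_johansen(df, horizon=15)
    km = lifelines.KaplanMeierFitter().fit(durations, observed)
    for _, row in curve.iterrows():
        s_km = float(km.survival_function_at_times(row["day"]).iloc[0])
        assert row["cif_death"] == pytest.approx(1 - s_km, abs=1e-12)


def test_weights_enter_as_ratios():
    df = aj_rows([(2, "death"), (3, "discharge"), (4, None)])
    df["weight"] = 0.7
    a = weighted_aalen_johansen(df, 4, weight_col="weight")
    df["weight"] = 1.4
    b = weighted_aalen_johansen(df, 4, weight_col="weight")
    pd.testing.assert_frame_equal(a, b)


def test_curve_identity_sums_to_one(null_run):
    for curve in (null_run["estimate"].curve_current, null_run["estimate"].curve_eliminated):
        total = curve["cif_death"] + curve["cif_discharge"] + curve["surv"]
        assert np.max(np.abs(total - 1.0)) < 1e-12
        assert (np.diff(curve["cif_death"]) >= -1e-15).all()
        assert (np.diff(curve["cif_discharge"]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# the contrast
# ---------------------------------------------------------------------------

def test_no_events_makes_both_scenarios_identical():
    ds = merge_datasets(
        *(plant_fixture([dict()] * 5, hosp_id=f"H{i}",
                        disposition="death" if i % 3 == 0 else "home")
          for i in range(9))
    )
    est = estimate_attributable(ds, EMPTY_EVENTS)
    assert est.risk_ratio == 1.0
    pd.testing.assert_frame_equal(est.curve_current, est.curve_eliminated)


def test_summary_arithmetic_identities(null_run):
    est = null_run["estimate"]
    assert est.risk_difference == pytest.approx(est.risk_current - est.risk_eliminated, abs=1e-12)
    assert est.attributable_fraction == pytest.approx(1 - est.risk_ratio, abs=1e-12)


def test_weighted_estimator_beats_naive_contrast_under_null(null_run):
    """With confounded onset and theta=1 the unweighted censor-at-onset
    contrast is biased away from 1; the IPW estimate is not."""
    ipw_rr = null_run["estimate"].risk_ratio
    naive_rr = null_run["naive_rr"]
    assert naive_rr < ipw_rr  # censoring the sick lowers apparent mortality
    assert abs(naive_rr - 1.0) > 2 * abs(ipw_rr - 1.0)


# ---------------------------------------------------------------------------
# pooling and strata
# ---------------------------------------------------------------------------

def _est(rr, n, reps=None):
    risk_cur = 2.0
    return AttributableEstimate(
        horizon=60,
        risk_current=risk_cur,
        risk_eliminated=rr * risk_cur,
        risk_difference=risk_cur * (1 - rr),
        risk_ratio=rr,
        attributable_fraction=1 - rr,
        n_hospitalizations=n,
        n_events=10,
        replicates=reps,
    )


class TestPooling:
    def test_single_site_is_identity(self):
        e = _est(0.9, 100)
        pooled = pool_sites([e], [100])
        assert pooled.risk_ratio == pytest.approx(0.9)

    def test_size_weighted_average(self):
        pooled = pool_sites([_est(0.9, 100_000), _est(1.0, 300_000)], [100_000, 300_000])
        assert pooled.risk_ratio == pytest.approx(0.975, abs=1e-12)

    def test_equal_sizes_give_plain_mean(self):
        pooled = pool_sites([_est(0.8, 50), _est(1.0, 50)], [50, 50])
        assert pooled.risk_ratio == pytest.approx(0.9)

    def test_mismatched_replicates_rejected(self):
        reps_a = pd.DataFrame({k: np.ones(5) for k in AttributableEstimate._FIELDS})
        reps_b = pd.DataFrame({k: np.ones(7) for k in AttributableEstimate._FIELDS})
        with pytest.raises(ValueError, match="replicate"):
            pool_sites([_est(0.9, 10, reps_a), _est(1.0, 10, reps_b)], [10, 10])


def test_all_stratum_matches_unstratified(null_run):
    sub = null_run["dataset"].subset(
        null_run["dataset"].hospitalizations["hosp_id"].iloc[:4000]
    )
    whole = estimate_attributable(sub, null_run["events"])
    strat = stratified_estimates(sub, null_run["events"], "all")
    assert list(strat) == ["all"]
    assert strat["all"].risk_ratio == pytest.approx(whole.risk_ratio, abs=1e-12)


def test_empty_stratum_is_not_estimable():
    young = [plant_fixture([dict()] * 4, hosp_id=f"H{i}", age=50) for i in range(6)]
    # the two old admissions are too short to enter the weighted cohort
    old = [plant_fixture([dict()] * 2, hosp_id=f"H9{i}", age=80) for i in range(2)]
    ds = merge_datasets(*(young + old))
    strat = stratified_estimates(
        ds, EMPTY_EVENTS, lambda h: np.where(h["age"] <= 65, "young", "old")
    )
    assert strat["young"] is not None
    assert strat["old"] is None  # reported as not estimable, not an abort


def test_thirty_day_horizon_supported(null_run):
    sub = null_run["dataset"].subset(
        null_run["dataset"].hospitalizations["hosp_id"].iloc[:4000]
    )
    est = estimate_attributable(sub, null_run["events"], CausalParams(horizon=30))
    assert est.horizon == 30
    assert est.curve_current["day"].max() == 30


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_cohort_zero_width():
    ds = merge_datasets(
        *(plant_fixture([dict()] * 4, hosp_id=f"H{i}") for i in range(6))
    )
    est = bootstrap_ci(ds, EMPTY_EVENTS, B=10, seed=3)
    lo, hi = est.ci["risk_ratio"]
    assert lo == hi == 1.0
    assert est.replicates["flagged_zero_events"].all()


def test_bootstrap_requires_two_replicates():
    ds = plant_fixture([dict()] * 4)
    with pytest.raises(ValueError, match="B"):
        bootstrap_ci(ds, EMPTY_EVENTS, B=1)
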