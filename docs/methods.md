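# Methods

## The surveillance definition

Non-ventilator-associated hospital-acquired pneumonia (NV-HAP) is detected
from structured EHR data alone. An admission meets the definition at the
first hospital day `d` where all four criteria hold:

1. **Sustained oxygenation deterioration.** Days `d` and `d+1` are each
   worse than the baseline day `d-1` — a strictly higher-ranked
   oxygen-delivery device (none < nasal cannula < simple mask < oxygen
   conserving device < nonrebreather < high-flow nasal cannula < BiPAP <
   ventilator) or an SpO2 at least δ points lower — after at least two
   stable-or-improving days (the `d-2 → d-1` transition, and `d-3 → d-2`
   when day `d-3` exists, are non-worsening under the same comparison).
   Hence the earliest possible onset is day 3.
2. **Systemic sign.** Temperature ≤36 °C or ≥38 °C, or white-cell count
   <4.0 or ≥12.0 ×10³/mm³ (thresholds inclusive exactly as written), on any
   day in `[d-2, d+2]`. Missing measurements never satisfy the criterion.
3. **Chest imaging** on any day in `[d-1, d+2]`.
4. **New antimicrobials.** A run of ≥3 consecutive days with at least one
   antimicrobial administration (agents may differ across days) starting on
   day `d` or `d+1`, with no administration in the preceding 2 days.
   A run truncated by discharge or death counts only if 3 days were
   observed.

Missing pulse oximetry and missing oxygen-device entries are treated as
normal (SpO2 97%, device "none"); the daily oxygenation summary fed to the
rule is the worst of the day (minimum SpO2, highest device rank). Patients
on a ventilator during both baseline days are excluded (their events would
be ventilator-associated pneumonia); patients ventilated *after* a
non-ventilated onset are retained. One event per admission: the first
qualifying day wins.

Several constants are not pinned down by the published definition and are
explicit, configurable package choices (`SurveillanceParams`): the SpO2
margin δ = 3 percentage points (a margin prevents 1-point oximetry jitter
from triggering events), the systemic-sign window `onset ± 2` days, the
imaging window `[onset-1, onset+2]`, and the 2-day "new antimicrobial"
lookback.

## The attributable-mortality estimand

The causal question is: how much of 60-day inpatient mortality would
disappear if NV-HAP could (hypothetically) be eliminated? Alive discharge
competes with inpatient death, and NV-HAP onset is a time-varying exposure
whose drivers (age, comorbidity burden, ICU stay, laboratory derangement)
also predict death, so a naive comparison is confounded and a regression on
post-onset status is exposed to time-dependent bias. The pipeline:

* **Cohort.** Admissions of ≥3 days with a day-1 or day-2 value for
  hospital service, wbc, hematocrit, platelets, sodium, glucose and
  creatinine. (wbc is required for entry but is not itself on the
  confounder list, which names hematocrit, platelets, sodium, glucose,
  creatinine.)
* **Person-days.** One row per admission-day, `t = 3 … min(los, 60)`.
  Time-varying covariates take the most recent measured value at or before
  `t-2` (last observation carried forward), plus `days_since_lab = t` minus
  the day of that last routine-lab panel (so a day-1 panel seen from `t=5`
  gives 4). Lag-2 values still unmeasured are filled with the cohort
  median, with `days_since_lab` carrying the staleness. Non-routine labs
  (ALT, bilirubin, albumin) enter as ordered categories including
  "not measured". Time zero is day 3 — the earliest possible onset given
  the two-day stable baseline; days 1–2 contribute only baseline and lagged
  covariates. Follow-up is administratively censored at day 60. Discharge
  to hospice is an alive discharge (a competing event), not a death.
* **Propensity model.** Pooled logistic regression of same-day onset on
  at-risk (event-free through `t-1`) person-days: a restricted cubic spline
  in `t` (4 knots at the 5/35/65/95th percentiles; a saturated categorical
  day effect is available and, with no covariates, reproduces the empirical
  per-day hazard exactly), facility size/teaching/region, age, sex, race,
  comorbidity flags, Elixhauser index, prior-90-day admission, and the
  lag-2 time-varying set (service, ICU, device rank, SpO2, the five routine
  labs, days-since-lab, non-routine lab categories). Numeric columns are
  standardized internally. On separation or divergence the model refits
  with a weak L2 penalty (α = 1e-4) and warns; zero onsets give the trivial
  model p̂ ≡ 0.
* **Elimination weights.** Follow-up is censored at onset; an event-free
  row at day `t` gets `W(t) = Π_{k=3..t} 1/(1 − p̂(k))`; the onset day and
  all later days get weight 0. A fitted p̂ = 1 aborts with a positivity
  error. Weights are unstabilized by default (a stabilized option divides
  by the marginal event-free probability) and truncated at the 99th
  percentile of positive weights. Cumulative onset probabilities are a few
  percent here, so weights stay near 1 and truncation rarely binds.
* **Weighted Aalen-Johansen.** Per day, cause-specific hazards
  `λ_e(t) = Σ W·I(event e at t) / Σ W` over rows present at `t`;
  `S(t) = Π (1 − λ_death − λ_discharge)`;
  `F_e(t) = Σ λ_e(s) S(s−1)`. The identity `F_death + F_discharge + S = 1`
  holds to 1e-12 at every day; days without at-risk mass get zero hazards.
  Current care uses the same estimator with unit weights and no censoring.
* **Contrast.** At the horizon: risk difference (current − eliminated),
  risk ratio RR (eliminated / current), attributable fraction `1 − RR`.
* **Inference.** Nonparametric bootstrap resampling hospitalizations
  (clusters) with replacement — 500 replicates by default, each refitting
  the propensity model — with percentile 2.5/97.5 intervals; deterministic
  given the seed. Replicates with zero events are recorded with RR 1 and
  flagged.
* **Multi-site pooling** averages site estimates (and their bootstrap
  replicates, replicate-by-replicate) with weights proportional to the
  number of unique hospitalizations per site. **Stratified runs** repeat
  the whole pipeline within strata (age group, service, ICU status,
  comorbidity quartile, hospital attributes) and support a 30-day horizon;
  an inestimable stratum is reported as such rather than aborting.

## The synthetic cohort generator

The source study is observational and publishes no generative model, so all
simulation parameters are artifact choices; the generator's job is to
produce data with the *structure* the pipeline needs and with known ground
truth, not to reproduce any particular health system's case mix.

Per admission: facility (bed-size class, teaching, region, a Dirichlet size
mix, and a facility-level onset intercept, SD 0.25 log-odds), age ~ N(64,
15²) truncated at 18, sex, race and service from realistic marginals, seven
comorbidity flags with van-Walraven-style weights summed (plus noise) into
the Elixhauser index, an exogenous initial ICU block whose odds rise with
severity, and lab trajectories (log-normal levels, daily jitter, a routine
panel measured with probability 0.95 on day 1 and 0.7 afterwards).

Per day, three draws in fixed order:

1. **Onset** (from day 3, never on a ventilated baseline, never after
   `max_followup − 2`): logistic in age, Elixhauser index, ICU two days
   prior, and the lag-2 LOCF creatinine — exactly the information an
   analyst can reconstruct from the emitted tables, so the propensity
   model's covariate span contains the true onset model.
2. **Death**: baseline hazard × `theta_death`^{post-onset} × a severity
   multiplier in age, Elixhauser and current ICU. Severity drives both
   onset and death: confounding is real, and the unweighted
   censor-at-onset contrast is measurably biased below 1 even when
   `theta_death = 1` (a property the tests assert).
3. **Alive discharge**: baseline hazard × `theta_discharge`^{post-onset}.

For every true event the tables receive a surveillance signature: a 2-rank
device escalation or a 6-point SpO2 drop on the onset day and the next two
days (always), and fever-or-leukocytosis, chest imaging, and a 3-day new
antimicrobial course each with probability `signal_completeness`. Terminal
events are suppressed on the onset day and the day after, so the 3-day
signature window always fits inside the stay and, with
`signal_completeness = 1` and zero background noise, detector sensitivity
and PPV are exactly 1 by construction. At a 60-day horizon with daily exit
hazards above 0.2, this two-day timing shift leaves the 60-day cause
distribution essentially unchanged, so it does not disturb the
`theta = 1` null. For the same reason ICU trajectories are exogenous — a
post-onset ICU transfer would open a real onset→ICU→death pathway and make
the null unrecoverable by design; `theta_death` is the only channel from
NV-HAP to death.

Defaults (`SimConfig`) emulate a general acute-care population: discharge
hazard 0.22/day (median stay ~4 days), death hazard 0.004/day (~2%
inpatient mortality), onset intercept −6.3 (roughly 0.5–1 true events per
100 admissions), `theta_death = 2`, `theta_discharge = 0.5` (post-event
stays lengthen), `signal_completeness = 0.9`.

**What the generator does not emulate:** real oximetry artefacts and
device-documentation noise, measurement-frequency differences between
hospitals, inter-hospital transfer, post-onset escalation of care, seasonal
or pandemic drift, and any particular network's case mix. Passing tests
therefore demonstrate correctness of the *rule engine and estimator* under
a known data-generating process, not the field accuracy of the definition.

## Simulation sizes used in tests

The estimator-validation suites (null recovery, effect direction) run on a
high-acuity configuration chosen for statistical resolution at n = 20 000:
onset intercept −3.9 (~7% cumulative onset, comparable to the sustained-
deterioration rate in general cohorts rather than confirmed NV-HAP) and
death hazard 0.01/day, with `theta_discharge = 1` so the death-hazard
multiplier is the only effect. Under `theta_death = 1` the estimated risk
ratio must land in [0.97, 1.03]; under `theta_death = 1.5` elimination must
lower the estimated risk in ≥19 of 20 seeds. At the defaults' paper-scale
event rate these checks would be dominated by Monte-Carlo noise at
desk-scale n. Brute-force oracle comparisons (rule engine, weighted
Aalen-Johansen) use 1000–1500 random instances at small n; the
Aalen-Johansen estimator is additionally checked against the Kaplan-Meier
complement (lifelines) when only one event type is present.

## Numerical choices and degenerate inputs

* Wilson score intervals for all binomial CIs (Clopper-Pearson by option);
  printed percentages round half-up.
* Cohen's kappa reports `(po, κ)` and returns κ = NaN (not estimable) when
  chance agreement is 1.
* Ties/tie-breaks: the first qualifying onset day wins; candidate days are
  scanned ascending.
* Zero admissions, zero events, empty strata and all-identical bootstrap
  cohorts are all defined (empty tables, identical current/elimination
  curves, "not estimable" entries, zero-width intervals respectively).
* All randomness flows from explicit integer seeds; the generator is
  byte-identical for a given seed and configuration.

## Known limitations

* The exact criterion windows, SpO2 margin, antimicrobial lookback,
  propensity functional form, weight stabilization and CI construction of
  the original surveillance programs are not restated in public sources;
  the package's defaults are documented choices, all configurable.
* The estimator assumes no unmeasured confounding given the listed
  covariates and positivity of the onset propensity; both are true of the
  synthetic generator by construction but must be argued, not assumed, on
  real data.
* Elixhauser/van Walraven scoring from diagnosis codes is out of scope:
  comorbidity flags and the index arrive as inputs.
* Chart-review κ values cannot be reproduced from published marginal
  counts; the kappa implementation is therefore verified at formula level
  (hand-computed tables, sklearn cross-check) only.
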