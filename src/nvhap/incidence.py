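"""Descriptive incidence reporting: event rates, facility variation, outcomes.

Rates are expressed per 100 admissions or per 1000 patient-days with Wilson
score intervals on the underlying proportion (Clopper-Pearson available).
Patient-day denominators count every calendar day of the stay, admission and
discharge days included (``los`` days per admission).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .ehr_model import Dataset, DISPOSITIONS

__all__ = [
    "RateEstimate",
    "UndefinedRateError",
    "rate",
    "facility_incidence",
    "outcome_table",
    "caterpillar_plot",
    "round_half_up",
]


class UndefinedRateError(ValueError):
    """A rate with a zero denominator is undefined."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed percentage tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEstimate:
    """A scaled event rate with its 95% CI."""

    numerator: int
    denominator: int
    scale: float  # 100 for per-100 admissions, 1000 for per-1000 patient-days
    rate: float
    ci_low: float
    ci_high: float


_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


def rate(
    numerator: int, denominator: int, scale: float = 100, method: str = "wilson"
) -> RateEstimate:
    """Events per ``scale`` units of the denominator with a binomial 95% CI."""
    if denominator <= 0:
        raise UndefinedRateError("rate undefined for denominator <= 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    if method not in _CI_METHODS:
        raise ValueError(f"method must be one of {sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method=_CI_METHODS[method])
    return RateEstimate(
        numerator=int(numerator),
        denominator=int(denominator),
        scale=float(scale),
        rate=scale * numerator / denominator,
        ci_low=float(scale * lo),
        ci_high=float(scale * hi),
    )


def facility_incidence(
    events: pd.DataFrame, hospitalizations: pd.DataFrame, method: str = "wilson"
) -> tuple[pd.DataFrame, dict]:
    """Per-facility event rates per 100 admissions, rank-ordered ascending.

    Returns the facility table and the median/IQR of facility rates (the
    summary shown beside a caterpillar plot).
    """
    h = hospitalizations
    denom = h.groupby("facility_id")["hosp_id"].nunique()
    ev = events.merge(h[["hosp_id", "facility_id"]], on="hosp_id", how="left")
    if ev["facility_id"].isna().any():
        raise ValueError("event with unresolvable facility")
    num = ev.groupby("facility_id")["hosp_id"].nunique().reindex(denom.index, fill_value=0)

    rows = []
    for fid in denom.index:
        est = rate(int(num[fid]), int(denom[fid]), scale=100, method=method)
        rows.append(
            {
                "facility_id": fid,
                "events": est.numerator,
                "admissions": est.denominator,
                "rate_per_100": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["rate_per_100", "facility_id"], kind="stable")
        .reset_index(drop=True)
    )
    rates = table["rate_per_100"]
    summary = {
        "median": float(rates.median()),
        "iqr": (float(rates.quantile(0.25)), float(rates.quantile(0.75))),
    }
    return table, summary


def outcome_table(
    events: pd.DataFrame, hospitalizations: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Disposition counts/percentages and length-of-stay for event vs all admissions."""
    h = hospitalizations
    ev_ids = set(events["hosp_id"]) if len(events) else set()
    groups = {"nvhap": h[h["hosp_id"].isin(ev_ids)], "all": h}

    rows = []
    for disp in DISPOSITIONS:
        row = {"disposition": disp}
        for name, g in groups.items():
            cnt = int((g["disposition"] == disp).sum())
            row[f"{name}_n"] = cnt
            row[f"{name}_pct"] = (
                round_half_up(100.0 * cnt / len(g), 1) if len(g) else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    los_summary = {}
    for name, g in groups.items():
        if len(g):
            los_summary[name] = {
                "median": float(g["los"].median()),
                "iqr": (float(g["los"].quantile(0.25)), float(g["los"].quantile(0.75))),
            }
        else:
            los_summary[name] = {"median": np.nan, "iqr": (np.nan, np.nan)}
    return table, los_summary


def caterpillar_plot(facility_table: pd.DataFrame, out_path) -> None:
    """Facilities ordered by incidence with 95% CI error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = facility_table.reset_index(drop=True)
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(max(6, len(t) * 0.12), 4))
    ax.errorbar(
        x,
        t["rate_per_100"],
        yerr=[t["rate_per_100"] - t["ci_low"], t["ci_high"] - t["rate_per_100"]],
        fmt="o",
        ms=3,
        color="black",
        ecolor="gray",
        elinewidth=0.8,
        capsize=0,
    )
    ax.set_xlabel("Facility (ranked by incidence)")
    ax.set_ylabel("Events per 100 admissions")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
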