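"""Validation statistics for dual-reviewer medical record review.

Positive predictive value of the electronic definition against a reference
judgment (with a Wilson 95% CI), and interrater agreement between the two
physician reviewers: simple agreement and Cohen's kappa,

    kappa = (po - pe) / (1 - pe),

where ``po`` is the observed agreement proportion and ``pe`` the agreement
expected from the raters' marginal proportions.  Kappa is not estimable when
``pe = 1`` (both raters constant in the same category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ppv", "cohen_kappa", "review_summary"]


@dataclass(frozen=True)
class PPVEstimate:
    positives: int
    reviewed: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> int:
        """Whole-percent display value (half-up)."""
        return int(np.floor(self.proportion * 100 + 0.5))


def ppv(positives: int, reviewed: int) -> PPVEstimate:
    """Positive predictive value with Wilson 95% CI."""
    if reviewed <= 0:
        raise ValueError("reviewed must be > 0")
    if not 0 <= positives <= reviewed:
        raise ValueError("positives must lie in [0, reviewed]")
    lo, hi = proportion_confint(positives, reviewed, alpha=0.05, method="wilson")
    return PPVEstimate(
        positives=int(positives),
        reviewed=int(reviewed),
        proportion=positives / reviewed,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def cohen_kappa(rater1: Sequence[bool], rater2: Sequence[bool]) -> tuple[float, float]:
    """Simple agreement and Cohen's kappa for paired binary judgments.

    Returns ``(po, kappa)``; kappa is ``nan`` (not estimable) when chance
    agreement ``pe`` equals 1.
    """
    a = np.asarray(rater1, dtype=bool)
    b = np.asarray(rater2, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1-d and equally long")
    n = len(a)
    if n == 0:
        raise ValueError("need at least one rated case")
    po = float(np.mean(a == b))
    p1, p2 = a.mean(), b.mean()
    pe = float(p1 * p2 + (1 - p1) * (1 - p2))
    if pe >= 1.0 - 1e-15:
        return po, float("nan")
    return po, (po - pe) / (1.0 - pe)


def review_summary(reviews: pd.DataFrame) -> dict:
    """Summary statistics for a review table.

    Expects columns ``case_id, reviewer1, reviewer2, clinician_documented,
    nhsn_met``.  Reports PPV of the electronic definition against (a) any of
    reviewer/bedside-clinician judgment and (b) NHSN criteria, plus reviewer
    agreement.
    """
    required = ["case_id", "reviewer1", "reviewer2", "clinician_documented", "nhsn_met"]
    missing = [c for c in required if c not in reviews.columns]
    if missing:
        raise ValueError(f"review table missing column(s): {', '.join(missing)}")
    n = len(reviews)
    r1 = reviews["reviewer1"].astype(bool)
    r2 = reviews["reviewer2"].astype(bool)
    any_positive = (r1 | r2 | reviews["clinician_documented"].astype(bool)).sum()
    nhsn = reviews["nhsn_met"].astype(bool).sum()
    po, kappa = cohen_kappa(r1, r2)

    ppv_any = ppv(int(any_positive), n)
    ppv_nhsn = ppv(int(nhsn), n)
    return {
        "n_reviewed": n,
        "ppv_clinical": {
            "proportion": ppv_any.proportion,
            "percent": ppv_any.percent,
            "ci": [ppv_any.ci_low, ppv_any.ci_high],
        },
        "ppv_nhsn": {
            "proportion": ppv_nhsn.proportion,
            "percent": ppv_nhsn.percent,
            "ci": [ppv_nhsn.ci_low, ppv_nhsn.ci_high],
        },
        "simple_agreement": po,
        "cohen_kappa": kappa,
    }
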