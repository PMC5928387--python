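"""Oncogenic-activity scoring and drug-inhibition calls.

Activity of a tested variant is expressed on a normalized percent scale
anchored by the wild-type (0%) and a known activating mutation (100%) of the
same gene on the same reporter:

    score = 100 * (NCR_VUS - NCR_WT) / (NCR_MT - NCR_WT)

A variant is called active when its score is >= 20%.  Drug response is read
from a 6-point log-spaced dose series: an active variant is called inhibited
when its activity drops below the same 20-point cutoff at any dose
("absolute" mode, the default).  A "relative" mode — activity falling below
20% of the untreated activity — is available as an alternative reading.

Significance of a variant-vs-wild-type NCR difference is assessed with a
two-sided two-sample t-test over well medians (Welch by default); the p-value
is reported alongside the score and does not gate the activity call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ACTIVITY_CUTOFF",
    "DOSE_RANGES_NM",
    "N_DOSES",
    "ActivityScore",
    "DoseResponseResult",
    "normalize_score",
    "ttest_vs_wt",
    "call_activity",
    "build_dose_series",
    "call_inhibition",
]

#: percent-scale cutoff shared by the activation and inhibition calls
ACTIVITY_CUTOFF = 20.0

#: printed dose ranges of the assayed MTAs, nM (low, high)
DOSE_RANGES_NM = {
    "sorafenib": (1.0, 1500.0),
    "imatinib": (2.5, 2500.0),
    "vemurafenib": (2.5, 2500.0),
    "lapatinib": (2.5, 2500.0),
}

N_DOSES = 6


@dataclass
class ActivityScore:
    """Normalized activity of one variant on one reporter pathway."""

    variant_id: str
    reporter_pathway: str = ""
    score: float | None = None  # percent on the WT(0)/MT(100) scale
    active: bool | None = None
    p_value: float | None = None
    ncr_vus: float | None = None
    ncr_wt: float | None = None
    ncr_mt: float | None = None

    def __post_init__(self) -> None:
        if self.active is None and self.score is not None:
            self.active = call_activity(self.score, self.p_value)


@dataclass
class DoseResponseResult:
    """Inhibition readout of one variant (or co-transfected combination)."""

    variant_id: str
    drug: str
    doses_nm: Sequence[float]
    activity_by_dose: Sequence[float]  # percent, same order as doses_nm
    untreated_activity: float
    inhibited: bool | None = None
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if len(self.doses_nm) != len(self.activity_by_dose):
            raise ValueError("doses and activities must have equal length")
        if self.inhibited is None:
            self.inhibited = call_inhibition(
                self.activity_by_dose, self.untreated_activity, mode=self.mode
            )


def normalize_score(ncr_vus: float, ncr_wt: float, ncr_mt: float) -> float:
    """Rescale a condition NCR to the percent activity scale.

    Returns 100 * (vus - wt) / (mt - wt); 0% at the wild-type anchor, 100% at
    the known-mutation anchor.  Values below 0 or above 100 are returned as
    computed, not clamped.
    """
    denom = ncr_mt - ncr_wt
    if denom == 0:
        raise ValueError("ncr_mt equals ncr_wt: activity scale undefined")
    return 100.0 * (ncr_vus - ncr_wt) / denom


def ttest_vs_wt(
    vus_well_medians: Sequence[float],
    wt_well_medians: Sequence[float],
    *,
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t-test p-value for variant vs wild-type well medians.

    Welch's unequal-variance form by default; ``equal_var=True`` selects the
    classic pooled form.  Two zero-variance groups with equal means give p = 1.
    """
    a = np.asarray(vus_well_medians, dtype=float)
    b = np.asarray(wt_well_medians, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 well medians per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def call_activity(score: float, p_value: float | None = None) -> bool:
    """Active iff score >= 20 (cutoff inclusive); p_value is informational only."""
    return score >= ACTIVITY_CUTOFF


def build_dose_series(drug: str) -> np.ndarray:
    """Six log-uniformly spaced doses (nM) spanning the drug's printed range."""
    key = drug.strip().lower()
    if key not in DOSE_RANGES_NM:
        raise ValueError(
            f"unknown drug {drug!r}; supported: {sorted(DOSE_RANGES_NM)}"
        )
    low, high = DOSE_RANGES_NM[key]
    return np.geomspace(low, high, N_DOSES)


def call_inhibition(
    activity_by_dose: Sequence[float],
    untreated_activity: float,
    *,
    mode: str = "absolute",
) -> bool:
    """Inhibition call for an active variant across its dose series.

    ``absolute`` (default): inhibited iff activity falls strictly below the
    20-point activation cutoff at any dose.  ``relative``: inhibited iff
    activity falls below 20% of the untreated activity at any dose.
    """
    if untreated_activity < ACTIVITY_CUTOFF:
        raise ValueError(
            "variant is not active untreated "
            f"(activity {untreated_activity} < {ACTIVITY_CUTOFF}); inhibition undefined"
        )
    lowest = float(np.min(np.asarray(activity_by_dose, dtype=float)))
    if mode == "absolute":
        return lowest < ACTIVITY_CUTOFF
    if mode == "relative":
        return lowest < 0.2 * untreated_activity
    raise ValueError(f"unknown inhibition mode {mode!r}; use 'absolute' or 'relative'")
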