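"""Survival comparison between prediction groups.

Progression-free survival (months) is compared between the positive- and
negative-prediction groups with group medians, a tie-corrected Kruskal-Wallis
rank test (chi-square approximation by default; an exact permutation p-value
is available for small cohorts), and Kaplan-Meier product-limit curves.  The
packaged cohort has an observed progression for every patient, so its KM
curves carry no censoring, but the estimator supports it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "SurvivalSummary",
    "GroupTestResult",
    "median_pfs",
    "round_months",
    "kruskal_wallis",
    "kaplan_meier",
    "summarize_groups",
    "plot_km",
]


@dataclass
class SurvivalSummary:
    group: str
    n: int
    median_pfs: float  # rounded to one decimal (half up)
    median_pfs_unrounded: float
    km_times: list[float]
    km_survival: list[float]


@dataclass
class GroupTestResult:
    h_statistic: float
    p_value: float
    tie_corrected: bool = True
    method: str = "chi-square"


def round_months(value: float, decimals: int = 1) -> float:
    """Round half up to the reporting precision (numpy/python round half to even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def median_pfs(pfs_values: Sequence[float], *, decimals: int | None = 1) -> float:
    """Sample median PFS; even counts average the central pair.

    Rounded half-up to ``decimals`` places (default one, the reporting
    convention); ``decimals=None`` returns the unrounded median.
    """
    values = np.asarray(pfs_values, dtype=float)
    if values.size == 0:
        raise ValueError("median_pfs: empty input")
    med = float(np.median(values))
    return med if decimals is None else round_months(med, decimals)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], *, method: str = "chi-square"
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H test across groups.

    ``method='chi-square'`` uses the chi-square approximation with k-1 degrees
    of freedom (standard software behaviour even at small n);
    ``method='permutation'`` computes an exact/enumerated permutation p-value
    for two groups, sharing the same H statistic.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, 1.0, True, method)
    h, p = stats.kruskal(*arrays)
    if method == "chi-square":
        return GroupTestResult(float(h), float(p), True, method)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if len(arrays) != 2:
        raise ValueError("permutation p-value implemented for two groups")
    n1 = arrays[0].size
    count = 0
    total = 0
    idx = np.arange(pooled.size)
    for subset in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(subset)] = True
        h_perm = stats.kruskal(pooled[mask], pooled[~mask]).statistic
        total += 1
        if h_perm >= h - 1e-12:
            count += 1
    return GroupTestResult(float(h), count / total, True, method)


def kaplan_meier(
    times: Sequence[float], events: Sequence[bool]
) -> tuple[list[float], list[float]]:
    """Product-limit survival estimate.

    Returns step-function support (starting at time 0 with survival 1) and the
    survival probability after each time.  Censored observations shrink the
    risk set without a downward step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_
    return [float(x) for x in surv.index], [float(v) for v in surv.iloc[:, 0]]


def summarize_groups(
    pfs_by_group: dict[str, Sequence[float]],
    events_by_group: dict[str, Sequence[bool]] | None = None,
    *,
    method: str = "chi-square",
) -> tuple[list[SurvivalSummary], GroupTestResult]:
    """Per-group survival summaries plus the between-group rank test."""
    summaries = []
    for group, values in pfs_by_group.items():
        events = (
            [True] * len(values)
            if events_by_group is None
            else list(events_by_group[group])
        )
        km_t, km_s = kaplan_meier(values, events)
        summaries.append(
            SurvivalSummary(
                group=group,
                n=len(values),
                median_pfs=median_pfs(values),
                median_pfs_unrounded=median_pfs(values, decimals=None),
                km_times=km_t,
                km_survival=km_s,
            )
        )
    test = kruskal_wallis(list(pfs_by_group.values()), method=method)
    return summaries, test


def stats_report(
    summaries: Sequence[SurvivalSummary], test: GroupTestResult
) -> dict:
    return {
        "groups": [
            {
                "group": s.group,
                "n": s.n,
                "median_pfs": s.median_pfs,
                "median_pfs_unrounded": s.median_pfs_unrounded,
                "km_times": s.km_times,
                "km_survival": s.km_survival,
            }
            for s in summaries
        ],
        "kruskal_wallis": {
            "h_statistic": test.h_statistic,
            "p_value": test.p_value,
            "tie_corrected": test.tie_corrected,
            "method": test.method,
        },
    }


def write_stats(
    summaries: Sequence[SurvivalSummary], test: GroupTestResult, path: str | Path
) -> None:
    Path(path).write_text(json.dumps(stats_report(summaries, test), indent=2))


def plot_km(summaries: Sequence[SurvivalSummary], path: str | Path) -> None:
    """Two-curve Kaplan-Meier plot (one step line per prediction group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for s in summaries:
        ax.step(s.km_times, s.km_survival, where="post", label=f"{s.group} (n={s.n})")
    ax.set_xlabel("PFS (months)")
    ax.set_ylabel("Survival fraction")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
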