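#!/usr/bin/env python
"""Progression-free survival contrast between prediction groups.

Reads results/predictions.csv, groups the cohort's PFS values by prediction
label, and writes group medians, the tie-corrected Kruskal-Wallis test and
Kaplan-Meier curves (JSON + plot).
"""

from pathlib import Path

import pandas as pd

from factpipe import clinical_stats, cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = cohort.load_cohort()
    labels = pd.read_csv(RESULTS / "predictions.csv").set_index("patient_id")["label"]
    pfs = {"positive": [], "negative": []}
    events = {"positive": [], "negative": []}
    for rec in records:
        pfs[labels[rec.patient_id]].append(rec.pfs_months)
        events[labels[rec.patient_id]].append(rec.event)
    summaries, test = clinical_stats.summarize_groups(pfs, events)
    clinical_stats.write_stats(summaries, test, RESULTS / "survival_stats.json")
    clinical_stats.plot_km(summaries, RESULTS / "km_curves.png")
    for s in summaries:
        print(
            f"  {s.group:8s} n={s.n}  median PFS {s.median_pfs} months "
            f"(unrounded {s.median_pfs_unrounded:.3f})"
        )
    print(f"Kruskal-Wallis H={test.h_statistic:.3f}, p={test.p_value:.4f}")
    print(f"wrote {RESULTS / 'survival_stats.json'}")


if __name__ == "__main__":
    main()
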