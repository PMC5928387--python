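#!/usr/bin/env python
"""Convert measured condition NCRs into normalized oncogenic-activity scores.

Reads results/condition_ncr.csv (written by 01_simulate_and_quantify.py),
rescales each test condition onto the WT(0%)/known-mutation(100%) activity
scale, attaches a Welch t-test p-value over the six well medians vs the
wild-type wells, and applies the 20% activity cutoff.
"""

from pathlib import Path

import pandas as pd

from factpipe.scoring import call_activity, normalize_score, ttest_vs_wt

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frame = pd.read_csv(RESULTS / "condition_ncr.csv").set_index("condition_id")
    medians = {
        cid: [float(x) for x in row["well_medians"].split(";")]
        for cid, row in frame.iterrows()
    }
    wt, mt = frame.loc["WT", "mean_ncr"], frame.loc["MT", "mean_ncr"]
    rows = []
    for cid, row in frame.iterrows():
        if cid in ("WT", "MT"):
            continue
        score = normalize_score(row["mean_ncr"], wt, mt)
        p = ttest_vs_wt(medians[cid], medians["WT"])
        active = call_activity(score, p)
        rows.append(
            {"condition_id": cid, "score": score, "p_value": p, "active": active}
        )
        print(f"  {cid:8s} score {score:6.1f}%  p={p:.2e}  active={active}")
    pd.DataFrame(rows).to_csv(RESULTS / "activity_scores.csv", index=False)
    print(f"wrote {RESULTS / 'activity_scores.csv'}")


if __name__ == "__main__":
    main()
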