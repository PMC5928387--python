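#!/usr/bin/env python
"""Patient-level survival predictions for the packaged 12-patient cohort.

Applies the decision rules (amplification/literature lookup, activity of
MTA-targeted variants, dose-response outcome of the co-transfected variant
set) to every patient and writes the prediction table.
"""

from pathlib import Path

from factpipe import cohort, prediction

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = cohort.load_cohort()
    predictions = prediction.predict_cohort(records)
    RESULTS.mkdir(exist_ok=True)
    prediction.write_predictions(predictions, RESULTS / "predictions.csv")
    n_pos = sum(p.label == "positive" for p in predictions)
    for p in predictions:
        print(f"  patient {p.patient_id:2d}: {p.label:8s} ({p.rationale})")
    print(f"{n_pos} positive / {len(predictions) - n_pos} negative")
    print(f"wrote {RESULTS / 'predictions.csv'}")


if __name__ == "__main__":
    main()
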