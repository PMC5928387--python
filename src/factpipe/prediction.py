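"""Patient-level survival prediction from assay results.

A patient's prediction is positive when the MTA given in the trial inhibited
the pathway activated by the patient's variant(s) in the assay, and negative
when the MTA failed to inhibit it or no assayed variant targeted by the MTA
was activating.  Patients treated on the basis of a gene amplification rather
than an assayed variant are resolved against a small literature table: a
matching (alteration, MTA) entry supplies the label, otherwise the MTA is not
assay-relevant and the prediction is negative.

Rule precedence in :func:`predict_patient`:

1. amplification-based treatment -> literature lookup;
2. no active variant among those targeted by the MTA -> negative;
3. otherwise the dose-response result of the patient's full (co-transfected)
   variant combination decides: inhibited -> positive, else negative.

The drug-to-gene-target map used by rule 2 ships as an editable CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import PatientRecord, Variant, data_path
from .scoring import ActivityScore, DoseResponseResult, build_dose_series

__all__ = [
    "Prediction",
    "LiteratureRule",
    "IncompleteAssayError",
    "load_literature_rules",
    "load_drug_targets",
    "mta_targets",
    "fixture_activities",
    "load_response_fixture",
    "predict_patient",
    "predict_cohort",
    "write_predictions",
]

_POSITIVE_RATIONALES = {"mta_inhibits", "literature_positive"}


@dataclass(frozen=True)
class Prediction:
    patient_id: int
    label: str  # "positive" | "negative"
    rationale: str  # mta_inhibits | mta_fails_to_inhibit | variant_not_activating |
    #                 mta_not_assay_relevant | literature_positive
    details: str = ""

    def __post_init__(self) -> None:
        if (self.label == "positive") != (self.rationale in _POSITIVE_RATIONALES):
            raise ValueError(
                f"patient {self.patient_id}: label {self.label!r} inconsistent "
                f"with rationale {self.rationale!r}"
            )


@dataclass(frozen=True)
class LiteratureRule:
    alteration: str  # e.g. "ERBB2 amplification"
    mta: str
    label: str  # "positive" | "negative"


class IncompleteAssayError(RuntimeError):
    """An active targeted variant has no dose-response result."""


def load_literature_rules(path: str | Path | None = None) -> list[LiteratureRule]:
    frame = pd.read_csv(path or data_path("literature_rules.csv"))
    rules = [
        LiteratureRule(r["alteration"], r["mta"], r["label"]) for _, r in frame.iterrows()
    ]
    keys = [(r.alteration, r.mta) for r in rules]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (alteration, mta) key in literature rules")
    return rules


def load_drug_targets(path: str | Path | None = None) -> dict[str, set[str]]:
    """Drug -> gene-target sets, from the packaged (or a user) CSV."""
    frame = pd.read_csv(path or data_path("drug_targets.csv"))
    targets: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        targets.setdefault(row["drug"].strip().lower(), set()).add(row["gene"])
    return targets


def mta_targets(mta: str, drug_targets: Mapping[str, set[str]]) -> set[str]:
    """Gene targets of an MTA regimen; combinations ('a + b') union their components."""
    genes: set[str] = set()
    for component in mta.split("+"):
        genes |= drug_targets.get(component.strip().lower(), set())
    return genes


def fixture_activities(
    records: Iterable[PatientRecord],
) -> dict[tuple[str, str], ActivityScore]:
    """Per-variant ActivityScore objects built from the cohort table's activity calls."""
    activities: dict[tuple[str, str], ActivityScore] = {}
    for rec in records:
        for v in rec.variants:
            if v.active is None:
                continue
            activities[v.key] = ActivityScore(
                variant_id=v.label, reporter_pathway=v.reporter_pathway, active=v.active
            )
    return activities


def _combo_key(combo_id: str) -> frozenset[tuple[str, str]]:
    pairs = []
    for part in combo_id.split("+"):
        gene, change = part.strip().split(":")
        pairs.append((gene, change))
    return frozenset(pairs)


def load_response_fixture(
    path: str | Path | None = None,
) -> dict[frozenset[tuple[str, str]], DoseResponseResult]:
    """Dose-response series for the MTA-tested variant combinations.

    The packaged table is synthetic: it encodes only the qualitative
    inhibition outcomes of the four assayed combinations (the three kinase
    inhibitors inhibit their single-variant targets; lapatinib does not
    inhibit ERBB2 T862A co-transfected with KRAS G12S) as smooth 6-point
    series on the percent activity scale.
    """
    frame = pd.read_csv(path or data_path("mta_response_synthetic.csv"))
    responses: dict[frozenset[tuple[str, str]], DoseResponseResult] = {}
    for combo_id, grp in frame.groupby("combo_id", sort=False):
        grp = grp.sort_values("dose_index")
        drug = grp["drug"].iloc[0]
        responses[_combo_key(str(combo_id))] = DoseResponseResult(
            variant_id=str(combo_id),
            drug=drug,
            doses_nm=build_dose_series(drug),
            activity_by_dose=grp["activity"].to_list(),
            untreated_activity=float(grp["untreated_activity"].iloc[0]),
        )
    return responses


def predict_patient(
    record: PatientRecord,
    activities: Mapping[tuple[str, str], ActivityScore],
    responses: Mapping[frozenset[tuple[str, str]], DoseResponseResult],
    literature: Sequence[LiteratureRule] | None = None,
    drug_targets: Mapping[str, set[str]] | None = None,
) -> Prediction:
    """Apply the decision rules to one patient. See module docstring for precedence."""
    literature = load_literature_rules() if literature is None else literature
    drug_targets = load_drug_targets() if drug_targets is None else drug_targets

    if record.treatment_basis == "amplification":
        for rule in literature:
            if (rule.alteration, rule.mta) == (record.basis_alteration, record.mta):
                return Prediction(
                    record.patient_id,
                    rule.label,
                    "literature_positive" if rule.label == "positive" else "mta_not_assay_relevant",
                    f"{record.mta} given for {record.basis_alteration}; literature rule",
                )
        return Prediction(
            record.patient_id,
            "negative",
            "mta_not_assay_relevant",
            f"{record.mta} given for {record.basis_alteration}; no literature support",
        )

    targets = mta_targets(record.mta, drug_targets)
    targeted_active = []
    for v in record.variants:
        if v.gene not in targets:
            continue
        score = activities.get(v.key)
        if score is None:
            raise IncompleteAssayError(
                f"patient {record.patient_id}: no activity result for {v.label}"
            )
        if score.active:
            targeted_active.append(v)
    if not targeted_active:
        return Prediction(
            record.patient_id,
            "negative",
            "variant_not_activating",
            "no MTA-targeted variant showed oncogenic activity",
        )

    response = responses.get(record.variant_combo)
    if response is None:
        raise IncompleteAssayError(
            f"patient {record.patient_id}: active targeted variant(s) "
            f"{[v.label for v in targeted_active]} without a dose-response result"
        )
    if response.inhibited:
        return Prediction(
            record.patient_id,
            "positive",
            "mta_inhibits",
            f"{response.drug} inhibited {response.variant_id}",
        )
    return Prediction(
        record.patient_id,
        "negative",
        "mta_fails_to_inhibit",
        f"{response.drug} failed to inhibit {response.variant_id}",
    )


def predict_cohort(
    records: Sequence[PatientRecord],
    activities: Mapping[tuple[str, str], ActivityScore] | None = None,
    responses: Mapping[frozenset[tuple[str, str]], DoseResponseResult] | None = None,
    literature: Sequence[LiteratureRule] | None = None,
    drug_targets: Mapping[str, set[str]] | None = None,
) -> list[Prediction]:
    """One prediction per patient; activity/response defaults come from the fixture."""
    if activities is None:
        activities = fixture_activities(records)
    if responses is None:
        responses = load_response_fixture()
    return [
        predict_patient(rec, activities, responses, literature, drug_targets)
        for rec in records
    ]


def write_predictions(predictions: Sequence[Prediction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "rationale": p.rationale,
                "details": p.details,
            }
            for p in predictions
        ]
    ).to_csv(path, index=False)
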