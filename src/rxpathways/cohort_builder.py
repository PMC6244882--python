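"""Cohort construction: eligibility, exclusions, index dates.

A patient enters the disease cohort when they (1) carry a qualifying
diagnosis, (2) carry no exclusion diagnosis at any date, (3) have a first
exposure to a disease-targeted drug (the index date), (4) have at least
``min_history_days`` of observation before the index date, and (5) remain on
continuous targeted treatment for at least ``min_treatment_days`` after it,
where exposure gaps up to ``max_gap_days`` are bridged into a single drug era
(the OHDSI persistence-window convention).

Defaults: 6 months history = 183 days, 1 year treatment = 365 days, 120-day
persistence window; all boundaries inclusive (>=).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cdm_tables import CdmDataset
from .pathway_extractor import to_ingredient_exposures

logger = logging.getLogger(__name__)

__all__ = [
    "CohortMember",
    "DiseaseDefinition",
    "EligibilityParams",
    "apply_exclusions",
    "build_cohort",
    "compute_index_date",
    "compute_index_dates",
    "find_diagnosed",
    "has_continuous_treatment",
    "has_prior_history",
    "merge_eras",
]


@dataclasses.dataclass(frozen=True)
class DiseaseDefinition:
    """Concept sets defining one disease: qualifying diagnoses, exclusion
    diagnoses (e.g. pregnancy, type 1 diabetes), and targeted ingredients."""

    name: str
    diagnosis_concepts: frozenset[int]
    exclusion_concepts: frozenset[int]
    target_drug_concepts: frozenset[int]

    def __post_init__(self):
        if self.diagnosis_concepts & self.exclusion_concepts:
            raise ValueError("diagnosis and exclusion concept sets must be disjoint")
        if not self.target_drug_concepts:
            raise ValueError("target drug concept set must be non-empty")

    @classmethod
    def from_mapping(cls, data: dict) -> "DiseaseDefinition":
        return cls(
            name=str(data["name"]),
            diagnosis_concepts=frozenset(int(c) for c in data["diagnosis_concepts"]),
            exclusion_concepts=frozenset(int(c) for c in data.get("exclusion_concepts", [])),
            target_drug_concepts=frozenset(int(c) for c in data["target_drug_concepts"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiseaseDefinition":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@dataclasses.dataclass(frozen=True)
class EligibilityParams:
    min_history_days: int = 183
    min_treatment_days: int = 365
    max_gap_days: int = 120

    def __post_init__(self):
        if min(self.min_history_days, self.min_treatment_days, self.max_gap_days) <= 0:
            raise ValueError("eligibility parameters must be positive")


@dataclasses.dataclass(frozen=True)
class CohortMember:
    person_id: int
    index_date: pd.Timestamp
    index_year: int


def find_diagnosed(dataset: CdmDataset, disease: DiseaseDefinition) -> set[int]:
    """Persons with at least one qualifying diagnosis record."""
    cond = dataset.condition_occurrences
    hit = cond["condition_concept_id"].isin(disease.diagnosis_concepts)
    return set(cond.loc[hit, "person_id"])


def apply_exclusions(
    dataset: CdmDataset, persons: set[int], disease: DiseaseDefinition
) -> set[int]:
    """Drop persons with any exclusion diagnosis, at any date (pre- or post-index)."""
    cond = dataset.condition_occurrences
    hit = cond["condition_concept_id"].isin(disease.exclusion_concepts)
    return persons - set(cond.loc[hit, "person_id"])


def compute_index_dates(
    dataset: CdmDataset, persons: set[int], disease: DiseaseDefinition
) -> dict[int, pd.Timestamp]:
    """Earliest target-drug exposure start per person; compound products are
    decomposed first, so a product containing a target ingredient qualifies.
    Persons with no target exposure are absent from the result."""
    exp = dataset.drug_exposures
    exp = exp[exp["person_id"].isin(persons)]
    exp = to_ingredient_exposures(exp, dataset.ingredient_map)
    exp = exp[exp["drug_concept_id"].isin(disease.target_drug_concepts)]
    if exp.empty:
        return {}
    firsts = exp.groupby("person_id")["drug_exposure_start_date"].min()
    return dict(firsts)


def compute_index_date(
    dataset: CdmDataset, person_id: int, disease: DiseaseDefinition
) -> pd.Timestamp | None:
    return compute_index_dates(dataset, {person_id}, disease).get(person_id)


def _observation_period(dataset: CdmDataset, person_id: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    obs = dataset.observation_periods
    row = obs[obs["person_id"] == person_id]
    if row.empty:
        raise ValueError(f"person {person_id} has no observation period")
    return row.iloc[0]["start_date"], row.iloc[0]["end_date"]


def has_prior_history(
    dataset: CdmDataset,
    person_id: int,
    index_date: pd.Timestamp,
    params: EligibilityParams = EligibilityParams(),
) -> bool:
    """True iff the observation period starts >= ``min_history_days`` before index."""
    start, end = _observation_period(dataset, person_id)
    if not (start <= index_date <= end):
        raise ValueError(
            f"index date {index_date.date()} outside observation period of person {person_id}"
        )
    return (index_date - start).days >= params.min_history_days


def merge_eras(
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]], max_gap_days: int
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Merge exposure intervals into drug eras, bridging gaps <= ``max_gap_days``."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    eras = [list(intervals[0])]
    for start, end in intervals[1:]:
        if (start - eras[-1][1]).days <= max_gap_days:
            eras[-1][1] = max(eras[-1][1], end)
        else:
            eras.append([start, end])
    return [(s, e) for s, e in eras]


def has_continuous_treatment(
    dataset: CdmDataset,
    person_id: int,
    index_date: pd.Timestamp,
    disease: DiseaseDefinition,
    params: EligibilityParams = EligibilityParams(),
) -> bool:
    """True iff the drug era containing the index date extends at least
    ``min_treatment_days`` past it."""
    exp = dataset.drug_exposures
    exp = exp[exp["person_id"] == person_id]
    exp = to_ingredient_exposures(exp, dataset.ingredient_map)
    exp = exp[exp["drug_concept_id"].isin(disease.target_drug_concepts)]
    intervals = list(
        zip(exp["drug_exposure_start_date"], exp["drug_exposure_end_date"])
    )
    for start, end in merge_eras(intervals, params.max_gap_days):
        if start <= index_date <= end:
            return (end - index_date).days >= params.min_treatment_days
    return False


def build_cohort(
    dataset: CdmDataset,
    disease: DiseaseDefinition,
    params: EligibilityParams = EligibilityParams(),
) -> list[CohortMember]:
    """Run the full eligibility funnel and return members ordered by person_id.

    Stages (each count logged at INFO): diagnosed -> after exclusions ->
    with a target-drug index date -> with prior history and continuous
    treatment (the cohort).
    """
    diagnosed = find_diagnosed(dataset, disease)
    logger.info("%s: diagnosed: %d", disease.name, len(diagnosed))
    kept = apply_exclusions(dataset, diagnosed, disease)
    logger.info("%s: after exclusions: %d", disease.name, len(kept))
    index_dates = compute_index_dates(dataset, kept, disease)
    logger.info("%s: with target-drug index date: %d", disease.name, len(index_dates))

    # Vectorized setup so eligibility runs in one pass over the exposure table.
    obs = dataset.observation_periods.drop_duplicates("person_id").set_index("person_id")
    exp = dataset.drug_exposures
    exp = exp[exp["person_id"].isin(index_dates)]
    exp = to_ingredient_exposures(exp, dataset.ingredient_map)
    exp = exp[exp["drug_concept_id"].isin(disease.target_drug_concepts)]
    intervals_by_person = {
        pid: list(zip(grp["drug_exposure_start_date"], grp["drug_exposure_end_date"]))
        for pid, grp in exp.groupby("person_id")
    }

    members = []
    for person_id in sorted(index_dates):
        index_date = index_dates[person_id]
        start, end = obs.loc[person_id, "start_date"], obs.loc[person_id, "end_date"]
        if not (start <= index_date <= end):
            raise ValueError(
                f"index date {index_date.date()} outside observation period of person {person_id}"
            )
        if (index_date - start).days < params.min_history_days:
            continue
        eras = merge_eras(intervals_by_person.get(person_id, []), params.max_gap_days)
        ok = any(
            s <= index_date <= e and (e - index_date).days >= params.min_treatment_days
            for s, e in eras
        )
        if not ok:
            continue
        members.append(
            CohortMember(person_id=person_id, index_date=index_date, index_year=index_date.year)
        )
    logger.info("%s: cohort: %d", disease.name, len(members))
    return members
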