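"""Treatment-pathway extraction and aggregation.

A pathway is the ordered sequence of *rounds* a patient receives: each round is
the set of disease-targeted ingredients whose first exposure falls on the same
date (a combination when initiated together). Only the first occurrence of an
ingredient counts — repeats and dose changes never reopen a round. Compound
products are decomposed into their constituent ingredients before extraction.
Extraction stops once a configurable number of distinct medications (default
20) has been recorded, or when no new ingredient appears.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

DEFAULT_CAP = 20

__all__ = [
    "DEFAULT_CAP",
    "PathwayEntry",
    "PathwaySummary",
    "TreatmentPathway",
    "aggregate_pathways",
    "extract_cohort_pathways",
    "extract_pathway",
    "parse_pathway_key",
    "pathway_key",
    "to_ingredient_exposures",
    "uniqueness_proportion",
    "write_summary_csv",
]

Rounds = tuple[tuple[int, ...], ...]


@dataclasses.dataclass(frozen=True)
class TreatmentPathway:
    """Ordered rounds of ingredient-concept sets for one patient.

    ``rounds`` stores each round as a tuple of concept ids sorted ascending;
    every ingredient appears in exactly one round (its first).
    """

    person_id: int
    rounds: Rounds

    def __post_init__(self):
        if not self.rounds or any(not r for r in self.rounds):
            raise ValueError("pathway rounds must be non-empty")
        flat = [i for r in self.rounds for i in r]
        if len(flat) != len(set(flat)):
            raise ValueError("an ingredient may appear in only one round")


@dataclasses.dataclass(frozen=True)
class PathwayEntry:
    rounds: Rounds
    key: str
    count: int


@dataclasses.dataclass
class PathwaySummary:
    """Pathway -> patient-count aggregation for one disease cohort.

    Entries are sorted by count descending, then key ascending; counts sum to
    ``total_patients``.
    """

    disease: str
    total_patients: int
    entries: list[PathwayEntry]


def pathway_key(rounds: Rounds, names: Mapping[int, str] | None = None) -> str:
    """Canonical ``"A+B>C"`` notation: rounds joined by ``>``, ingredients within
    a round sorted by concept id and joined by ``+``. ``names`` substitutes
    concept names for ids when provided."""
    label = (lambda i: names[i]) if names else str
    return ">".join("+".join(label(i) for i in sorted(r)) for r in rounds)


def parse_pathway_key(key: str) -> Rounds:
    """Inverse of :func:`pathway_key` for id-based keys."""
    return tuple(tuple(sorted(int(i) for i in part.split("+"))) for part in key.split(">"))


def to_ingredient_exposures(
    exposures: pd.DataFrame,
    ingredient_map: pd.DataFrame,
    product_concepts: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Rewrite drug exposures at ingredient level.

    Product-level exposures (concept present in ``ingredient_map``) become one
    exposure per constituent ingredient with identical dates; ingredient-level
    exposures pass through unchanged. Duplicate (person, ingredient, dates)
    rows are collapsed.

    ``product_concepts``, when given, lists every concept id that is
    product-level; a product missing from the map is then a fatal error
    naming the concept.
    """
    exposures = exposures.copy()
    mapped = set(ingredient_map["drug_concept_id"])
    if product_concepts is not None:
        unmapped = set(product_concepts) & set(exposures["drug_concept_id"]) - mapped
        if unmapped:
            raise ValueError(
                f"product concept(s) missing from ingredient map: {sorted(unmapped)}"
            )
    is_product = exposures["drug_concept_id"].isin(mapped)
    plain = exposures.loc[~is_product]
    expanded = exposures.loc[is_product].merge(
        ingredient_map, on="drug_concept_id", how="left"
    )
    expanded["drug_concept_id"] = expanded["ingredient_concept_id"].astype("int64")
    expanded = expanded[plain.columns]
    out = pd.concat([plain, expanded], ignore_index=True)
    out = out.drop_duplicates(
        ["person_id", "drug_concept_id", "drug_exposure_start_date", "drug_exposure_end_date"]
    )
    return out.reset_index(drop=True)


def extract_pathway(
    person_exposures: pd.DataFrame,
    index_date: pd.Timestamp,
    drug_universe: Iterable[int] | None = None,
    cap: int = DEFAULT_CAP,
) -> Rounds:
    """Extract one patient's rounds from ingredient-level exposures.

    Ingredients are ordered by first-exposure date on/after ``index_date``;
    ingredients tied on that date form one combination round. When recording a
    round would exceed ``cap`` distinct ingredients, the round is truncated
    keeping its lowest concept ids and extraction stops.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    df = person_exposures
    if drug_universe is not None:
        df = df[df["drug_concept_id"].isin(set(drug_universe))]
    df = df[df["drug_exposure_start_date"] >= index_date]
    if df.empty:
        raise ValueError("no qualifying exposures on/after the index date")
    first = df.groupby("drug_concept_id")["drug_exposure_start_date"].min()
    rounds: list[tuple[int, ...]] = []
    n = 0
    for _, grp in sorted(first.groupby(first), key=lambda kv: kv[0]):
        ingredients = sorted(grp.index)
        room = cap - n
        if room <= 0:
            break
        ingredients = ingredients[:room]
        rounds.append(tuple(ingredients))
        n += len(ingredients)
    return tuple(rounds)


def extract_cohort_pathways(
    dataset,
    cohort: Sequence,
    target_drug_concepts: Iterable[int],
    cap: int = DEFAULT_CAP,
) -> list[TreatmentPathway]:
    """Extract pathways for every cohort member of a :class:`CdmDataset`.

    ``cohort`` is a sequence of objects with ``person_id`` and ``index_date``
    (see ``cohort_builder.CohortMember``); exposures are first decomposed to
    ingredient level and restricted to the disease's target drugs.
    """
    targets = set(target_drug_concepts)
    exposures = to_ingredient_exposures(dataset.drug_exposures, dataset.ingredient_map)
    exposures = exposures[exposures["drug_concept_id"].isin(targets)]
    by_person = dict(tuple(exposures.groupby("person_id")))
    out = []
    for member in cohort:
        rounds = extract_pathway(by_person[member.person_id], member.index_date, cap=cap)
        out.append(TreatmentPathway(person_id=member.person_id, rounds=rounds))
    return out


def aggregate_pathways(
    pathways: Iterable[TreatmentPathway],
    disease: str = "",
    names: Mapping[int, str] | None = None,
) -> PathwaySummary:
    """Count patients per canonical pathway, sorted by count desc then key asc."""
    counts: dict[Rounds, int] = {}
    total = 0
    for pw in pathways:
        counts[pw.rounds] = counts.get(pw.rounds, 0) + 1
        total += 1
    entries = [
        PathwayEntry(rounds=r, key=pathway_key(r, names), count=c) for r, c in counts.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.key))
    return PathwaySummary(disease=disease, total_patients=total, entries=entries)


def uniqueness_proportion(summary: PathwaySummary) -> float:
    """Fraction of patients whose pathway is shared with no other patient."""
    if summary.total_patients < 1:
        raise ValueError("empty summary")
    unique = sum(e.count for e in summary.entries if e.count == 1)
    return unique / summary.total_patients


def write_summary_csv(summary: PathwaySummary, path: str | Path) -> None:
    rows = [
        {
            "disease": summary.disease,
            "pathway": e.key,
            "n_patients": e.count,
            "fraction": e.count / summary.total_patients if summary.total_patients else 0.0,
        }
        for e in summary.entries
    ]
    pd.DataFrame(rows, columns=["disease", "pathway", "n_patients", "fraction"]).to_csv(
        path, index=False
    )
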