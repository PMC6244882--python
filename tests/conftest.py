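"""Shared fixtures: a reference disease, dataset builders, brute-force oracles."""

from __future__ import annotations

import pandas as pd
import pytest

from rxpathways.cdm_tables import CdmDataset, dataset_from_records
from rxpathways.cohort_builder import DiseaseDefinition
from rxpathways.pathway_extractor import (
    PathwayEntry,
    PathwaySummary,
    parse_pathway_key,
    pathway_key,
)
from rxpathways.synthetic_data import GeneratorConfig, PathwayTemplate

BASE = pd.Timestamp("2010-01-01")

DIAGNOSIS = 1000
EXCLUSION = 2000
TARGETS = frozenset({1, 2, 3, 4, 5})


def day(offset: int) -> pd.Timestamp:
    """Calendar date *offset* days after the fixture epoch."""
    return BASE + pd.Timedelta(days=offset)


@pytest.fixture
def disease() -> DiseaseDefinition:
    return DiseaseDefinition(
        name="diabetes",
        diagnosis_concepts=frozenset({DIAGNOSIS}),
        exclusion_concepts=frozenset({EXCLUSION}),
        target_drug_concepts=TARGETS,
    )


def standard_concepts(products: dict[int, tuple[int, ...]] | None = None) -> list[tuple]:
    """Concept rows covering the fixture disease's drugs and diagnoses."""
    rows = [(c, f"ingredient_{c}", "ingredient") for c in sorted(TARGETS)]
    rows += [
        (DIAGNOSIS, "diagnosis", "condition"),
        (EXCLUSION, "exclusion", "condition"),
    ]
    for pid, _ in sorted((products or {}).items()):
        rows.append((pid, f"product_{pid}", "clinical_drug"))
    return rows


def toy_dataset(
    persons=(),
    observation_periods=(),
    condition_occurrences=(),
    drug_exposures=(),
    products: dict[int, tuple[int, ...]] | None = None,
) -> CdmDataset:
    """Hand-built dataset over the fixture concept universe.

    ``products`` maps product concept id -> constituent ingredient ids and
    populates both the concept table and the ingredient map.
    """
    imap = [
        (pid, ing) for pid, ings in sorted((products or {}).items()) for ing in ings
    ]
    return dataset_from_records(
        persons=persons,
        observation_periods=observation_periods,
        condition_occurrences=condition_occurrences,
        drug_exposures=drug_exposures,
        concepts=standard_concepts(products),
        ingredient_map=imap,
    )


def make_config(disease: DiseaseDefinition, **overrides) -> GeneratorConfig:
    """Generator config with a two-template default mix, overridable per test."""
    defaults = dict(
        n_patients=100,
        disease=disease,
        templates=(
            PathwayTemplate(rounds=((1,),), probability=0.5),
            PathwayTemplate(rounds=((1,), (2,)), probability=0.5),
        ),
        seed=12345,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def brute_force_rounds(records, index_date, cap=20):
    """Independent pathway reference: first-exposure date per ingredient,
    sorted, ties grouped. ``records`` is an iterable of (ingredient, start)."""
    firsts: dict[int, pd.Timestamp] = {}
    for ingredient, start in records:
        if start < index_date:
            continue
        if ingredient not in firsts or start < firsts[ingredient]:
            firsts[ingredient] = start
    rounds, seen = [], 0
    for date in sorted(set(firsts.values())):
        tied = sorted(i for i, d in firsts.items() if d == date)
        tied = tied[: cap - seen]
        if not tied:
            break
        rounds.append(tuple(tied))
        seen += len(tied)
    return tuple(rounds)


def summary_from(entries: list[tuple[str, int]], disease: str = "d") -> PathwaySummary:
    """Build a summary straight from ("1+2>3", count) pairs, canonically sorted."""
    built = [
        PathwayEntry(rounds=parse_pathway_key(key), key=key, count=count)
        for key, count in entries
    ]
    built.sort(key=lambda e: (-e.count, e.key))
    return PathwaySummary(
        disease=disease, total_patients=sum(e.count for e in built), entries=built
    )


def merge_datasets(a: CdmDataset, b: CdmDataset) -> CdmDataset:
    """Concatenate two datasets with disjoint person ids (concepts deduplicated)."""
    frames = {}
    for attr in ("persons", "observation_periods", "condition_occurrences",
                 "drug_exposures", "concepts", "ingredient_map"):
        frames[attr] = (
            pd.concat([getattr(a, attr), getattr(b, attr)], ignore_index=True)
            .drop_duplicates()
            .reset_index(drop=True)
        )
    return CdmDataset(**frames)


assert pathway_key(((1, 2), (3,))) == "1+2>3"  # notation sanity for helpers above
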