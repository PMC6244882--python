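"""Medication-consistency indexes and their calendar-year trends.

Three indexes summarize how uniformly a disease cohort is medicated:

1. **Monotherapy proportion** — patients whose whole medication sequence is a
   single drug, over the cohort.
2. **Common-monotherapy proportion** — patients whose whole sequence is
   exactly the cohort's most common drug, over a configurable denominator.
3. **First-line proportion** — patients whose first round contains the most
   common drug, over the cohort.

For trends, patients are grouped by index year. The most common drug is
determined once from the whole cohort and held fixed across years. The
common-monotherapy trend defaults to the *monotherapy patients of that year*
as denominator, while the static index defaults to the whole cohort; both
denominators are available and the one used is flagged in every output row.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .pathway_extractor import PathwaySummary, TreatmentPathway, aggregate_pathways

__all__ = [
    "ConsistencyIndexes",
    "common_monotherapy_proportion",
    "compute_indexes",
    "first_line_proportion",
    "monotherapy_proportion",
    "most_common_first_drug",
    "write_indexes_csv",
    "write_trends_csv",
    "yearly_trends",
]

TREND_COLUMNS = [
    "disease",
    "index_year",
    "n",
    "monotherapy_prop",
    "common_mono_prop",
    "common_mono_denominator",
    "first_line_prop",
]


@dataclasses.dataclass(frozen=True)
class ConsistencyIndexes:
    monotherapy_proportion: float
    common_monotherapy_proportion: float
    first_line_most_common_proportion: float
    most_common_first_drug: int


def _require_nonempty(summary: PathwaySummary) -> None:
    if summary.total_patients < 1:
        raise ValueError("empty pathway summary")


def _is_monotherapy(rounds) -> bool:
    return len(rounds) == 1 and len(rounds[0]) == 1


def monotherapy_proportion(summary: PathwaySummary) -> float:
    """Fraction of patients on exactly one drug for their whole sequence.

    A combination started on day one (e.g. ``A+B``) is not monotherapy.
    """
    _require_nonempty(summary)
    mono = sum(e.count for e in summary.entries if _is_monotherapy(e.rounds))
    return mono / summary.total_patients


def most_common_first_drug(summary: PathwaySummary) -> int:
    """Ingredient appearing in the most patients' first rounds; ties go to the
    smaller concept id."""
    _require_nonempty(summary)
    tally: dict[int, int] = {}
    for e in summary.entries:
        for ingredient in e.rounds[0]:
            tally[ingredient] = tally.get(ingredient, 0) + e.count
    return min(tally, key=lambda i: (-tally[i], i))


def common_monotherapy_proportion(
    summary: PathwaySummary, drug: int, denominator: str = "cohort"
) -> float:
    """Fraction of patients whose entire pathway is exactly ``[[drug]]``.

    ``denominator`` is ``"cohort"`` (all patients) or ``"monotherapy"`` (only
    monotherapy patients); returns 0 for an empty monotherapy denominator.
    """
    _require_nonempty(summary)
    if denominator not in ("cohort", "monotherapy"):
        raise ValueError(f"unknown denominator {denominator!r}")
    hits = sum(e.count for e in summary.entries if e.rounds == ((drug,),))
    if denominator == "cohort":
        denom = summary.total_patients
    else:
        denom = sum(e.count for e in summary.entries if _is_monotherapy(e.rounds))
    return hits / denom if denom else 0.0


def first_line_proportion(summary: PathwaySummary, drug: int) -> float:
    """Fraction of patients whose first round contains ``drug`` (membership,
    not sole occupancy)."""
    _require_nonempty(summary)
    hits = sum(e.count for e in summary.entries if drug in e.rounds[0])
    return hits / summary.total_patients


def compute_indexes(summary: PathwaySummary) -> ConsistencyIndexes:
    """The three static indexes with whole-cohort denominators."""
    drug = most_common_first_drug(summary)
    return ConsistencyIndexes(
        monotherapy_proportion=monotherapy_proportion(summary),
        common_monotherapy_proportion=common_monotherapy_proportion(
            summary, drug, denominator="cohort"
        ),
        first_line_most_common_proportion=first_line_proportion(summary, drug),
        most_common_first_drug=drug,
    )


def yearly_trends(
    cohort: Sequence,
    pathways: Iterable[TreatmentPathway],
    most_common_drug: int | None = None,
    common_mono_denominator: str = "monotherapy",
    disease: str = "",
) -> pd.DataFrame:
    """Per-index-year trend table for the three indexes.

    ``cohort`` members carry ``person_id`` and ``index_year``. The most common
    drug defaults to the whole-cohort argmax and is held fixed across years;
    years with no patients are omitted.
    """
    year_of = {m.person_id: m.index_year for m in cohort}
    pathways = list(pathways)
    if most_common_drug is None:
        most_common_drug = most_common_first_drug(aggregate_pathways(pathways))
    by_year: dict[int, list[TreatmentPathway]] = {}
    for pw in pathways:
        by_year.setdefault(year_of[pw.person_id], []).append(pw)
    rows = []
    for year in sorted(by_year):
        summary = aggregate_pathways(by_year[year])
        rows.append(
            {
                "disease": disease,
                "index_year": year,
                "n": summary.total_patients,
                "monotherapy_prop": monotherapy_proportion(summary),
                "common_mono_prop": common_monotherapy_proportion(
                    summary, most_common_drug, denominator=common_mono_denominator
                ),
                "common_mono_denominator": common_mono_denominator,
                "first_line_prop": first_line_proportion(summary, most_common_drug),
            }
        )
    return pd.DataFrame(rows, columns=TREND_COLUMNS)


def write_trends_csv(trends: pd.DataFrame, path: str | Path) -> None:
    trends.to_csv(path, index=False)


def write_indexes_csv(
    indexes: ConsistencyIndexes, path: str | Path, disease: str = ""
) -> None:
    pd.DataFrame(
        [
            {
                "disease": disease,
                "monotherapy_prop": indexes.monotherapy_proportion,
                "common_mono_prop": indexes.common_monotherapy_proportion,
                "common_mono_denominator": "cohort",
                "first_line_prop": indexes.first_line_most_common_proportion,
                "most_common_first_drug": indexes.most_common_first_drug,
            }
        ]
    ).to_csv(path, index=False)
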