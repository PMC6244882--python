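"""Minimal OMOP CDM v5 table subset: typed in-memory bundle, CSV I/O, validation.

Only the tables a treatment-pathway analysis touches are modelled: PERSON,
OBSERVATION_PERIOD, CONDITION_OCCURRENCE, DRUG_EXPOSURE, CONCEPT plus a flat
product-to-ingredient map (the one slice of CONCEPT_ANCESTOR the analysis needs).
Dates are ISO-8601 calendar dates; durations are whole days; intervals are
half-open [start, end) unless noted. Each person has at most one observation
period.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = [
    "CdmDataset",
    "CdmError",
    "TABLE_COLUMNS",
    "empty_dataset",
    "read_cdm",
    "validate_cdm",
    "write_cdm",
]

#: canonical column order per table (file stem == table name + ".csv")
TABLE_COLUMNS: dict[str, list[str]] = {
    "person": ["person_id", "gender_concept_id", "year_of_birth"],
    "observation_period": ["person_id", "start_date", "end_date"],
    "condition_occurrence": ["person_id", "condition_concept_id", "condition_start_date"],
    "drug_exposure": [
        "person_id",
        "drug_concept_id",
        "drug_exposure_start_date",
        "drug_exposure_end_date",
    ],
    "concept": ["concept_id", "concept_name", "concept_class"],
    "ingredient_map": ["drug_concept_id", "ingredient_concept_id"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "observation_period": ["start_date", "end_date"],
    "condition_occurrence": ["condition_start_date"],
    "drug_exposure": ["drug_exposure_start_date", "drug_exposure_end_date"],
}

CONCEPT_CLASSES = frozenset({"ingredient", "clinical_drug", "condition"})

#: dataclass attribute -> table name
_ATTR_TO_TABLE = {
    "persons": "person",
    "observation_periods": "observation_period",
    "condition_occurrences": "condition_occurrence",
    "drug_exposures": "drug_exposure",
    "concepts": "concept",
    "ingredient_map": "ingredient_map",
}


class CdmError(ValueError):
    """Fatal structural problem with CDM input (missing file, bad row, bad schema)."""


@dataclasses.dataclass
class CdmDataset:
    """In-memory bundle of the CDM table subset, one DataFrame per table."""

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    condition_occurrences: pd.DataFrame
    drug_exposures: pd.DataFrame
    concepts: pd.DataFrame
    ingredient_map: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        """Map table name -> DataFrame, in canonical order."""
        return {table: getattr(self, attr) for attr, table in _ATTR_TO_TABLE.items()}

    def copy(self) -> "CdmDataset":
        return CdmDataset(**{attr: getattr(self, attr).copy() for attr in _ATTR_TO_TABLE})


def _empty_table(table: str) -> pd.DataFrame:
    df = pd.DataFrame({col: pd.Series(dtype=object) for col in TABLE_COLUMNS[table]})
    return _coerce_types(df, table)


def _coerce_types(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in TABLE_COLUMNS[table]:
        if col in DATE_COLUMNS.get(table, []):
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
        elif col.endswith("_id") or col == "year_of_birth":
            df[col] = df[col].astype("int64")
        else:
            df[col] = df[col].astype(str) if len(df) else df[col].astype(object)
    return df[TABLE_COLUMNS[table]]


def empty_dataset() -> CdmDataset:
    return CdmDataset(**{attr: _empty_table(table) for attr, table in _ATTR_TO_TABLE.items()})


def dataset_from_records(**tables) -> CdmDataset:
    """Build a dataset from row tuples in canonical column order.

    Keyword arguments are the :class:`CdmDataset` field names; omitted tables
    are empty. Convenience constructor for generators and test fixtures.
    """
    unknown = set(tables) - set(_ATTR_TO_TABLE)
    if unknown:
        raise TypeError(f"unknown table(s): {sorted(unknown)}")
    frames = {}
    for attr, table in _ATTR_TO_TABLE.items():
        rows = list(tables.get(attr, ()))
        if not rows:
            frames[attr] = _empty_table(table)
        else:
            frames[attr] = _coerce_types(pd.DataFrame(rows, columns=TABLE_COLUMNS[table]), table)
    return CdmDataset(**frames)


def read_cdm(directory: str | Path) -> CdmDataset:
    """Read the six CSV tables from *directory* into a :class:`CdmDataset`.

    Raises :class:`CdmError` naming the file for a missing table, or naming the
    row for an unparsable value. Dates must be ISO-8601.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for attr, table in _ATTR_TO_TABLE.items():
        path = directory / f"{table}.csv"
        if not path.exists():
            raise CdmError(f"missing CDM table file: {path}")
        df = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[])
        missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
        if missing:
            raise CdmError(f"{path.name}: missing columns {missing}")
        try:
            frames[attr] = _coerce_types(df, table)
        except (ValueError, TypeError) as exc:
            frames[attr] = _locate_bad_row(df, table, path.name, exc)
    return CdmDataset(**frames)


def _locate_bad_row(df: pd.DataFrame, table: str, filename: str, exc: Exception):
    """Re-parse row by row so the error can name the offending data row."""
    for i in range(len(df)):
        try:
            _coerce_types(df.iloc[[i]].copy(), table)
        except (ValueError, TypeError):
            raise CdmError(f"{filename}: malformed value in row {i + 1}: {exc}") from exc
    raise CdmError(f"{filename}: malformed table: {exc}") from exc


def write_cdm(dataset: CdmDataset, directory: str | Path) -> None:
    """Write *dataset* as six CSVs readable by :func:`read_cdm` (lossless round trip)."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CdmError(f"cannot create output directory {directory}: {exc}") from exc
    for table, df in dataset.tables().items():
        out = df.copy()
        for col in DATE_COLUMNS.get(table, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / f"{table}.csv", index=False)


def _append_row_violations(violations: list[str], table: str, mask: pd.Series, rule: str) -> None:
    for row in mask.index[mask]:
        violations.append(f"{table}: row {row}: {rule}")


def validate_cdm(dataset: CdmDataset) -> list[str]:
    """Return all invariant violations as human-readable strings (empty == valid).

    Violations are data, not exceptions: each names the table, the row and the
    rule it breaks. Checked: uniqueness, value ranges, date ordering, one
    observation period per person, events inside the observation period, and
    referential integrity of person and concept identifiers.
    """
    v: list[str] = []
    persons = dataset.persons
    obs = dataset.observation_periods
    cond = dataset.condition_occurrences
    drug = dataset.drug_exposures
    concepts = dataset.concepts
    imap = dataset.ingredient_map

    _append_row_violations(v, "person", persons["person_id"].duplicated(), "duplicate person_id")
    _append_row_violations(
        v,
        "person",
        ~persons["year_of_birth"].between(1900, 2025),
        "year_of_birth outside [1900, 2025]",
    )
    _append_row_violations(v, "concept", concepts["concept_id"].duplicated(), "duplicate concept_id")
    if len(concepts):
        _append_row_violations(
            v,
            "concept",
            ~concepts["concept_class"].isin(CONCEPT_CLASSES),
            f"concept_class not in {sorted(CONCEPT_CLASSES)}",
        )

    _append_row_violations(
        v, "observation_period", obs["end_date"] < obs["start_date"], "end_date before start_date"
    )
    _append_row_violations(
        v,
        "observation_period",
        obs["person_id"].duplicated(),
        "more than one observation period for person",
    )

    known_persons = set(persons["person_id"])
    period = obs.drop_duplicates("person_id").set_index("person_id")

    for table, df, date_cols in (
        ("observation_period", obs, []),
        ("condition_occurrence", cond, ["condition_start_date"]),
        ("drug_exposure", drug, ["drug_exposure_start_date"]),
    ):
        _append_row_violations(
            v, table, ~df["person_id"].isin(known_persons), "person_id not in person table"
        )
        for col in date_cols:
            starts = period["start_date"].reindex(df["person_id"]).to_numpy()
            ends = period["end_date"].reindex(df["person_id"]).to_numpy()
            inside = (starts <= df[col].to_numpy()) & (df[col].to_numpy() <= ends)
            has_period = df["person_id"].isin(period.index).to_numpy()
            mask = pd.Series(has_period & ~inside, index=df.index)
            _append_row_violations(v, table, mask, f"{col} outside observation period")

    _append_row_violations(
        v,
        "drug_exposure",
        drug["drug_exposure_end_date"] < drug["drug_exposure_start_date"],
        "end date before start date",
    )

    known_concepts = set(concepts["concept_id"])
    _append_row_violations(
        v,
        "condition_occurrence",
        ~cond["condition_concept_id"].isin(known_concepts),
        "condition_concept_id not in concept table",
    )
    _append_row_violations(
        v,
        "drug_exposure",
        ~drug["drug_concept_id"].isin(known_concepts),
        "drug_concept_id not in concept table",
    )

    ingredient_ids = set(concepts.loc[concepts["concept_class"] == "ingredient", "concept_id"])
    _append_row_violations(
        v,
        "ingredient_map",
        ~imap["ingredient_concept_id"].isin(ingredient_ids),
        "ingredient_concept_id is not an ingredient concept",
    )
    return v
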