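"""Synthetic CDM generator with a known answer key.

Generates a :class:`~rxpathways.cdm_tables.CdmDataset` in which every person is
either (a) an eligible patient realizing one of a set of configured pathway
templates — guaranteed to pass every cohort-eligibility predicate and to yield
exactly the template's rounds under extraction — or (b) a noise patient planted
to fail exactly one predicate: too little pre-index history (``short_history``),
treatment stopping before one year (``early_dropout``), or an exclusion
diagnosis (``excluded_dx``). The ground-truth label, intended index date and
intended pathway per person form the answer key for downstream tests.

Randomness is a single seeded stream split per person from (seed, person_id),
so output is byte-identical for identical config + seed and independent of
generation order. Index dates are drawn uniformly over the configured year
range and history lengths uniformly over their range; neither distribution is
meant to mimic real visit timing, only to exercise the eligibility windows.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdm_tables import TABLE_COLUMNS, CdmDataset, _coerce_types, _empty_table
from .cohort_builder import DiseaseDefinition, EligibilityParams
from .pathway_extractor import Rounds, parse_pathway_key, pathway_key

__all__ = [
    "GeneratorConfig",
    "PathwayTemplate",
    "config_from_yaml",
    "eligible_ids",
    "generate",
    "read_ground_truth",
    "write_ground_truth",
]

NOISE_LABELS = ("short_history", "early_dropout", "excluded_dx")

_GENDERS = (8507, 8532)  # OMOP male / female
_PRODUCT_ID_BASE = 9_000_000


@dataclasses.dataclass(frozen=True)
class PathwayTemplate:
    """One ground-truth pathway: ordered ingredient rounds plus its population
    share and exposure timing (days between round starts, days each exposure
    lasts)."""

    rounds: Rounds
    probability: float
    inter_round_gap_days: int = 90
    exposure_span_days: int = 60

    def __post_init__(self):
        rounds = tuple(tuple(sorted(int(i) for i in r)) for r in self.rounds)
        object.__setattr__(self, "rounds", rounds)
        if not rounds or any(not r for r in rounds):
            raise ValueError("template rounds must be non-empty")
        flat = [i for r in rounds for i in r]
        if len(flat) != len(set(flat)):
            raise ValueError("template ingredients must be distinct across rounds")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("template probability must be in [0, 1]")
        if self.inter_round_gap_days <= 0 or self.exposure_span_days <= 0:
            raise ValueError("timing parameters must be positive")

    @property
    def ingredients(self) -> set[int]:
        return {i for r in self.rounds for i in r}


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int
    disease: DiseaseDefinition
    templates: tuple[PathwayTemplate, ...]
    index_year_range: tuple[int, int] = (2005, 2015)
    history_days_range: tuple[int, int] = (183, 1460)
    frac_short_history: float = 0.0
    frac_early_dropout: float = 0.0
    frac_excluded_dx: float = 0.0
    compound_product_prob: float = 0.0
    seed: int = 0
    person_id_offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "templates", tuple(self.templates))
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total_p = sum(t.probability for t in self.templates)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"template probabilities sum to {total_p}, expected 1")
        fracs = (self.frac_short_history, self.frac_early_dropout, self.frac_excluded_dx)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("noise fractions must lie in [0, 1] and sum to <= 1")
        if self.index_year_range[0] > self.index_year_range[1]:
            raise ValueError("index_year_range must be (first, last) with first <= last")
        if not 0 <= self.history_days_range[0] <= self.history_days_range[1]:
            raise ValueError("history_days_range must be non-degenerate and non-negative")
        params = EligibilityParams()
        if self.history_days_range[0] < params.min_history_days:
            raise ValueError(
                "infeasible config: eligible history range must start at "
                f">= {params.min_history_days} days"
            )
        for t in self.templates:
            gap = t.inter_round_gap_days - t.exposure_span_days
            if len(t.rounds) > 1 and gap > params.max_gap_days:
                raise ValueError(
                    "infeasible config: exposure_span_days too short — the "
                    f"{gap}-day gap between rounds exceeds the {params.max_gap_days}-day "
                    "persistence window, breaking treatment continuity"
                )
        if self.frac_excluded_dx > 0 and not self.disease.exclusion_concepts:
            raise ValueError("frac_excluded_dx > 0 requires exclusion concepts")
        used = {i for t in self.templates for i in t.ingredients}
        if not used <= self.disease.target_drug_concepts:
            raise ValueError("template ingredients must be target drugs of the disease")


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    templates = tuple(
        PathwayTemplate(
            rounds=tuple(tuple(r) for r in t["rounds"]),
            probability=float(t["probability"]),
            inter_round_gap_days=int(t.get("inter_round_gap_days", 90)),
            exposure_span_days=int(t.get("exposure_span_days", 60)),
        )
        for t in data["templates"]
    )
    kwargs = {
        k: data[k]
        for k in (
            "n_patients",
            "frac_short_history",
            "frac_early_dropout",
            "frac_excluded_dx",
            "compound_product_prob",
            "seed",
            "person_id_offset",
        )
        if k in data
    }
    for k in ("index_year_range", "history_days_range"):
        if k in data:
            kwargs[k] = tuple(data[k])
    return GeneratorConfig(
        disease=DiseaseDefinition.from_mapping(data["disease"]),
        templates=templates,
        **kwargs,
    )


def _assign_product_ids(config: GeneratorConfig) -> dict[Rounds, int]:
    """Stable product concept id per multi-ingredient round, in template order."""
    ids: dict[Rounds, int] = {}
    for t in config.templates:
        for r in t.rounds:
            if len(r) >= 2 and (r,) not in ids:
                ids[(r,)] = _PRODUCT_ID_BASE + len(ids)
    taken = {i for t in config.templates for i in t.ingredients}
    taken |= config.disease.diagnosis_concepts | config.disease.exclusion_concepts
    if taken & set(ids.values()):
        raise ValueError("configured concept ids collide with generated product ids")
    return ids


def generate(config: GeneratorConfig) -> tuple[CdmDataset, pd.DataFrame]:
    """Generate a dataset plus its ground-truth answer key.

    The answer key is a DataFrame with one row per person: ``person_id``,
    ``label`` (``template_<i>`` or a noise label), ``index_date`` (the intended
    index) and ``pathway`` (the intended rounds in ``"A+B>C"`` notation).
    """
    disease = config.disease
    probs = np.array([t.probability for t in config.templates])
    probs = probs / probs.sum()
    cum_noise = np.cumsum(
        [config.frac_short_history, config.frac_early_dropout, config.frac_excluded_dx]
    )
    product_ids = _assign_product_ids(config)

    persons, periods, conditions, exposures, truth = [], [], [], [], []

    for i in range(config.n_patients):
        pid = config.person_id_offset + i
        rng = np.random.default_rng([config.seed, pid])

        u = rng.random()
        label = "eligible"
        for frac, name in zip(cum_noise, NOISE_LABELS):
            if u < frac:
                label = name
                break
        t_idx = int(rng.choice(len(config.templates), p=probs))
        template = config.templates[t_idx]
        if label == "eligible":
            label = f"template_{t_idx}"

        year = int(rng.integers(config.index_year_range[0], config.index_year_range[1] + 1))
        index = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))
        if label == "short_history":
            history_days = int(rng.integers(0, EligibilityParams().min_history_days))
        else:
            history_days = int(
                rng.integers(config.history_days_range[0], config.history_days_range[1] + 1)
            )
        obs_start = index - pd.Timedelta(days=history_days)

        # Exposure schedule realizing the template's rounds in order.
        rows = []  # (concept_id, start, end, is_last_round)
        n_rounds = len(template.rounds)
        for r, round_ in enumerate(template.rounds):
            rstart = index + pd.Timedelta(days=r * template.inter_round_gap_days)
            rend = rstart + pd.Timedelta(days=template.exposure_span_days)
            as_product = (
                len(round_) >= 2 and rng.random() < config.compound_product_prob
            )
            concepts_here = [product_ids[(round_,)]] if as_product else list(round_)
            for cid in concepts_here:
                rows.append([cid, rstart, rend, r == n_rounds - 1])

        # Guarantee >= 1 year of continuous treatment past index for
        # template-labelled persons by stretching the final round's exposures.
        tail_end = index + pd.Timedelta(days=int(rng.integers(366, 500)))
        for row in rows:
            if row[3] and row[2] < tail_end:
                row[2] = tail_end

        if label == "early_dropout":
            cutoff = index + pd.Timedelta(days=int(rng.integers(30, 301)))
            rows = [
                [cid, s, min(e, cutoff), last]
                for cid, s, e, last in rows
                if s < cutoff
            ]

        obs_end = max(e for _, _, e, _ in rows) + pd.Timedelta(days=int(rng.integers(30, 366)))

        dx = int(rng.choice(sorted(disease.diagnosis_concepts)))
        dx_date = index - pd.Timedelta(days=int(rng.integers(0, history_days + 1)))
        conditions.append((pid, dx, dx_date))
        if label == "excluded_dx":
            ex = int(rng.choice(sorted(disease.exclusion_concepts)))
            ex_date = index - pd.Timedelta(days=int(rng.integers(0, history_days + 1)))
            conditions.append((pid, ex, ex_date))

        persons.append((pid, int(rng.choice(_GENDERS)), int(rng.integers(1930, 1991))))
        periods.append((pid, obs_start, obs_end))
        exposures.extend((pid, cid, s, e) for cid, s, e, _ in rows)
        truth.append((pid, label, index, pathway_key(template.rounds)))

    dataset = CdmDataset(
        persons=_frame("person", persons),
        observation_periods=_frame("observation_period", periods),
        condition_occurrences=_frame("condition_occurrence", conditions),
        drug_exposures=_frame("drug_exposure", exposures),
        concepts=_concept_table(config, product_ids),
        ingredient_map=_ingredient_map(product_ids),
    )
    truth_df = pd.DataFrame(truth, columns=["person_id", "label", "index_date", "pathway"])
    return dataset, truth_df


def _frame(table: str, rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return _empty_table(table)
    return _coerce_types(pd.DataFrame(rows, columns=TABLE_COLUMNS[table]), table)


def _concept_table(config: GeneratorConfig, product_ids: dict[Rounds, int]) -> pd.DataFrame:
    rows = []
    for cid in sorted(config.disease.target_drug_concepts):
        rows.append((cid, f"ingredient_{cid}", "ingredient"))
    for cid in sorted(config.disease.diagnosis_concepts | config.disease.exclusion_concepts):
        rows.append((cid, f"condition_{cid}", "condition"))
    for (round_,), pid_ in sorted(product_ids.items(), key=lambda kv: kv[1]):
        rows.append((pid_, "product_" + "_".join(map(str, round_)), "clinical_drug"))
    return _frame("concept", rows)


def _ingredient_map(product_ids: dict[Rounds, int]) -> pd.DataFrame:
    rows = [
        (pid_, ing)
        for (round_,), pid_ in sorted(product_ids.items(), key=lambda kv: kv[1])
        for ing in round_
    ]
    return _frame("ingredient_map", rows)


def eligible_ids(truth: pd.DataFrame) -> set[int]:
    """Person ids the answer key marks as cohort-eligible."""
    return set(truth.loc[truth["label"].str.startswith("template_"), "person_id"])


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    out = truth.copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": "int64", "label": str, "pathway": str})
    df["index_date"] = pd.to_datetime(df["index_date"], format="ISO8601")
    # validate pathway notation eagerly so corrupt files fail here, not downstream
    df["pathway"].map(parse_pathway_key)
    return df
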