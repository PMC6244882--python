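"""Eligibility predicates, era construction, and full cohort assembly."""

import dataclasses

import pytest

from rxpathways.cohort_builder import (
    CohortMember,
    DiseaseDefinition,
    EligibilityParams,
    apply_exclusions,
    build_cohort,
    compute_index_date,
    find_diagnosed,
    has_continuous_treatment,
    has_prior_history,
    merge_eras,
)
from rxpathways.synthetic_data import eligible_ids, generate

from conftest import DIAGNOSIS, EXCLUSION, day, make_config, toy_dataset


def person_rows(*pids):
    return [(p, 8507, 1960) for p in pids]


class TestDiagnosisAndExclusion:
    def test_no_condition_rows_means_empty(self, disease):
        ds = toy_dataset(persons=person_rows(1), observation_periods=[(1, day(0), day(10))])
        assert find_diagnosed(ds, disease) == set()

    def test_only_diagnosed_persons_selected(self, disease):
        ds = toy_dataset(
            persons=person_rows(1, 2, 3),
            observation_periods=[(p, day(0), day(10)) for p in (1, 2, 3)],
            condition_occurrences=[(1, DIAGNOSIS, day(1)), (2, DIAGNOSIS, day(1))],
        )
        assert find_diagnosed(ds, disease) == {1, 2}

    def test_exclusion_concept_alone_does_not_diagnose(self, disease):
        ds = toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(0), day(10))],
            condition_occurrences=[(1, EXCLUSION, day(1))],
        )
        assert find_diagnosed(ds, disease) == set()

    def test_exclusion_record_removes_person_any_date(self, disease):
        ds = toy_dataset(
            persons=person_rows(1, 2),
            observation_periods=[(p, day(0), day(500)) for p in (1, 2)],
            condition_occurrences=[(1, EXCLUSION, day(400))],  # post-index still excludes
        )
        assert apply_exclusions(ds, {1, 2}, disease) == {2}

    def test_empty_exclusion_set_is_identity(self, disease):
        bare = dataclasses.replace(disease, exclusion_concepts=frozenset())
        ds = toy_dataset(persons=person_rows(1))
        assert apply_exclusions(ds, {1}, bare) == {1}

    def test_planted_exclusions_leave_the_rest(self, disease):
        ds = toy_dataset(
            persons=person_rows(1, 2, 3, 4, 5),
            observation_periods=[(p, day(0), day(10)) for p in range(1, 6)],
            condition_occurrences=[(p, DIAGNOSIS, day(1)) for p in range(1, 6)]
            + [(2, EXCLUSION, day(2)), (4, EXCLUSION, day(2))],
        )
        assert apply_exclusions(ds, find_diagnosed(ds, disease), disease) == {1, 3, 5}


class TestIndexDate:
    def test_earliest_target_exposure_wins(self, disease):
        ds = toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(0), day(500))],
            drug_exposures=[(1, 1, day(40), day(60)), (1, 1, day(10), day(30))],
        )
        assert compute_index_date(ds, 1, disease) == day(10)

    def test_no_target_exposure_gives_none(self, disease):
        ds = toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(0), day(500))],
            drug_exposures=[(1, 2, day(10), day(30))],  # ingredient 2, not a target below
        )
        narrow = dataclasses.replace(disease, target_drug_concepts=frozenset({1}))
        assert compute_index_date(ds, 1, narrow) is None

    def test_compound_product_decomposed_before_min(self, disease):
        ds = toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(0), day(500))],
            drug_exposures=[(1, 900, day(5), day(30)), (1, 1, day(9), day(30))],
            products={900: (1, 2)},
        )
        assert compute_index_date(ds, 1, disease) == day(5)


class TestHistoryPredicate:
    @pytest.mark.parametrize(
        "history_days, expected",
        [(200, True), (100, False), (183, True)],  # 183 is the inclusive boundary
    )
    def test_history_threshold(self, disease, history_days, expected):
        ds = toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(0), day(1000))],
        )
        assert has_prior_history(ds, 1, day(history_days)) is expected

    def test_index_outside_period_signals_inconsistent_data(self, disease):
        ds = toy_dataset(
            persons=person_rows(1), observation_periods=[(1, day(0), day(100))]
        )
        with pytest.raises(ValueError, match="outside observation period"):
            has_prior_history(ds, 1, day(200))


class TestContinuousTreatment:
    def _ds(self, exposures):
        return toy_dataset(
            persons=person_rows(1),
            observation_periods=[(1, day(-400), day(1200))],
            drug_exposures=[(1, 1, day(s), day(e)) for s, e in exposures],
        )

    def test_single_long_exposure(self, disease):
        assert has_continuous_treatment(self._ds([(0, 400)]), 1, day(0), disease)

    def test_bridgeable_gap_within_persistence_window(self, disease):
        ds = self._ds([(0, 100), (150, 400)])  # 50-day gap bridged
        assert has_continuous_treatment(ds, 1, day(0), disease)

    def test_unbridgeable_gap_breaks_the_era(self, disease):
        ds = self._ds([(0, 100), (300, 800)])  # 200-day gap > 120
        assert not has_continuous_treatment(ds, 1, day(0), disease)

    def test_era_merge_oracle(self):
        eras = merge_eras(
            [(day(0), day(100)), (day(150), day(400)), (day(600), day(700))], 120
        )
        assert eras == [(day(0), day(400)), (day(600), day(700))]


class TestBuildCohort:
    def test_all_noise_dataset_yields_empty_cohort(self, disease):
        # one-third each noise class: nobody remains eligible
        ds, truth = generate(
            make_config(
                disease,
                n_patients=30,
                frac_short_history=1 / 3,
                frac_early_dropout=1 / 3,
                frac_excluded_dx=1 / 3,
            )
        )
        assert eligible_ids(truth) == set()
        assert build_cohort(ds, disease) == []

    def test_cohort_equals_answer_key_with_noise(self, disease):
        ds, truth = generate(
            make_config(
                disease,
                n_patients=500,
                frac_short_history=0.1,
                frac_early_dropout=0.1,
                frac_excluded_dx=0.1,
                seed=31,
            )
        )
        cohort = build_cohort(ds, disease)
        assert {m.person_id for m in cohort} == eligible_ids(truth)

    def test_single_eligible_person_has_correct_index_year(self, disease):
        ds, truth = generate(make_config(disease, n_patients=1, index_year_range=(2008, 2008)))
        (member,) = build_cohort(ds, disease)
        assert member.index_year == member.index_date.year == 2008

    def test_member_order_is_by_person_id(self, disease):
        ds, _ = generate(make_config(disease, n_patients=50))
        ids = [m.person_id for m in build_cohort(ds, disease)]
        assert ids == sorted(ids)

    def test_monotonicity_of_eligibility_parameters(self, disease):
        ds, _ = generate(
            make_config(disease, n_patients=200, frac_early_dropout=0.2, seed=8)
        )
        base = {m.person_id for m in build_cohort(ds, disease)}
        stricter_gap = {
            m.person_id
            for m in build_cohort(ds, disease, EligibilityParams(max_gap_days=20))
        }
        longer_treatment = {
            m.person_id
            for m in build_cohort(ds, disease, EligibilityParams(min_treatment_days=450))
        }
        assert stricter_gap <= base
        assert longer_treatment <= base

    def test_filter_accounting_logged_and_monotone(self, disease, caplog):
        import logging

        ds, _ = generate(
            make_config(disease, n_patients=100, frac_excluded_dx=0.2, seed=4)
        )
        with caplog.at_level(logging.INFO, logger="rxpathways.cohort_builder"):
            build_cohort(ds, disease)
        counts = [int(r.getMessage().rsplit(" ", 1)[1]) for r in caplog.records]
        assert len(counts) == 4
        assert counts == sorted(counts, reverse=True)
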