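"""Synthetic cohort generator: apportionment, dispensing simulation,
ground-truth accounting, and model/generator agreement."""

import math

import numpy as np
import pandas as pd
import pytest

import pharmprev as pp
from pharmprev.synthetic import STATUSES, largest_remainder


@pytest.fixture()
def config():
    return pp.CohortConfig(
        n_pop=100_000,
        true_prevalence=0.10,
        undiagnosed_fraction=0.40,
        insulin_t2dm_fraction=0.075,
        t1dm_prevalence=0.005,
        mode="deterministic",
        seed=11,
    )


class TestLargestRemainder:
    def test_counts_sum_to_total_and_track_quotas(self):
        counts = largest_remainder(100, [0.333, 0.333, 0.334])
        assert counts.sum() == 100
        quotas = 100 * np.array([0.333, 0.333, 0.334])
        assert (np.abs(counts - quotas) < 1).all()

    def test_exact_quotas_untouched(self):
        assert list(largest_remainder(10, [0.5, 0.3, 0.2])) == [5, 3, 2]


class TestGenerateCohort:
    def test_deterministic_counts_are_exact_expected_values(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        counts = persons.status.value_counts()
        # 10,000 T2DM: 4,000 undiagnosed, 6,000 treated of whom 7.5% = 450
        # use insulin; plus 500 T1DM
        assert counts["t2dm_undiagnosed"] == 4000
        assert counts["t2dm_nad"] == 5550
        assert counts["t2dm_insulin"] == 450
        assert counts["t1dm"] == 500
        assert counts["healthy"] == 89_500

    def test_zero_prevalence_means_no_antidiabetic_exposure(self, registry):
        cfg = pp.CohortConfig(
            n_pop=1000, true_prevalence=0.0, t1dm_prevalence=0.0,
            mode="deterministic", seed=0,
        )
        persons = pp.generate_cohort(cfg, registry)
        assert set(persons.status) == {"healthy"}
        records = pp.simulate_dispensing(persons, registry, cfg)
        assert records.empty

    def test_same_seed_identical_cohort(self, registry):
        cfg = pp.CohortConfig(n_pop=5000, mode="stochastic", seed=42)
        first = pp.generate_cohort(cfg, registry)
        second = pp.generate_cohort(cfg, registry)
        pd.testing.assert_frame_equal(first, second)
        records_first = pp.simulate_dispensing(first, registry, cfg)
        records_second = pp.simulate_dispensing(second, registry, cfg)
        pd.testing.assert_frame_equal(records_first, records_second)

    def test_statuses_carry_correct_regimens(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        sizes = persons.regimen.map(len)
        assert (sizes[persons.status.isin(["healthy", "t2dm_undiagnosed"])] == 0).all()
        assert (sizes[persons.status.isin(["t2dm_insulin", "t1dm"])] == 1).all()
        nad = persons[persons.status == "t2dm_nad"]
        assert sizes[nad.index].between(1, 4).all()
        # insulin users carry insulin codes only, never NADs
        insulin_rows = persons[persons.status.isin(["t2dm_insulin", "t1dm"])]
        assert all(
            pp.classify_ad(code) == "insulin"
            for regimen in insulin_rows.regimen for code in regimen
        )
        assert all(
            pp.classify_ad(code) == "nad"
            for regimen in nad.regimen for code in regimen
        )

    def test_regimen_holds_distinct_chemical_subgroups(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        for regimen in persons[persons.status == "t2dm_nad"].regimen:
            subgroups = [pp.atc_level(code, 4) for code in regimen]
            assert len(subgroups) == len(set(subgroups))

    def test_regimen_sizes_follow_configured_probabilities(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        sizes = persons[persons.status == "t2dm_nad"].regimen.map(len)
        observed = sizes.value_counts(normalize=True).sort_index()
        for k, pi in enumerate(config.regimen_probs, start=1):
            assert observed.get(k, 0.0) == pytest.approx(pi, abs=1e-3)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum above 1"):
            pp.CohortConfig(true_prevalence=0.9, t1dm_prevalence=0.2)
        with pytest.raises(ValueError, match="regimen_probs"):
            pp.CohortConfig(regimen_probs=(0.5, 0.5, 0.5, -0.5))


class TestSimulateDispensing:
    def test_one_monotherapy_patient_year(self, registry):
        cfg = pp.CohortConfig(
            n_pop=1, true_prevalence=1.0, undiagnosed_fraction=0.0,
            insulin_t2dm_fraction=0.0, t1dm_prevalence=0.0,
            regimen_probs=(1.0, 0.0, 0.0, 0.0), adherence_nad=1.0,
            mode="deterministic", seed=1,
        )
        persons = pp.generate_cohort(cfg, registry)
        records = pp.simulate_dispensing(persons, registry, cfg)
        total = sum(pp.record_total_ddd(row, registry)
                    for row in records.to_dict("records"))
        assert total == pytest.approx(365.0)

    def test_triple_therapy_partial_adherence(self, registry):
        cfg = pp.CohortConfig(
            n_pop=1, true_prevalence=1.0, undiagnosed_fraction=0.0,
            insulin_t2dm_fraction=0.0, t1dm_prevalence=0.0,
            regimen_probs=(0.0, 0.0, 1.0, 0.0), adherence_nad=0.6,
            mode="deterministic", seed=1,
        )
        persons = pp.generate_cohort(cfg, registry)
        records = pp.simulate_dispensing(persons, registry, cfg)
        total = sum(pp.record_total_ddd(row, registry)
                    for row in records.to_dict("records"))
        assert total == pytest.approx(3 * 0.6 * 365)

    def test_t1dm_person_generates_only_insulin_records(self, registry):
        cfg = pp.CohortConfig(
            n_pop=1, true_prevalence=0.0, t1dm_prevalence=1.0 - 1e-9,
            mode="deterministic", seed=1,
        )
        persons = pp.generate_cohort(cfg, registry)
        assert list(persons.status) == ["t1dm"]
        records = pp.simulate_dispensing(persons, registry, cfg)
        assert all(pp.classify_ad(code) == "insulin" for code in records.atc)

    def test_pack_quantisation_rounds_units_up(self, registry):
        base = dict(
            n_pop=10, true_prevalence=1.0, undiagnosed_fraction=0.0,
            insulin_t2dm_fraction=0.0, t1dm_prevalence=0.0,
            regimen_probs=(1.0, 0.0, 0.0, 0.0), adherence_nad=0.6,
            mode="deterministic", seed=5,
        )
        loose = pp.simulate_dispensing(
            pp.generate_cohort(pp.CohortConfig(**base), registry),
            registry, pp.CohortConfig(**base),
        )
        packed_cfg = pp.CohortConfig(**base, pack_size=56)
        packed = pp.simulate_dispensing(
            pp.generate_cohort(packed_cfg, registry), registry, packed_cfg
        )
        assert packed.n_units.sum() >= loose.n_units.sum()
        assert (packed.n_units % 1 == 0).all()


class TestTrueSummary:
    def test_exact_counting(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        summary = pp.true_summary(persons).set_index("region")
        total = summary.loc["TOTAL"]
        assert total.n == 100_000
        assert total.treated_prev_pct == pytest.approx(6.0)  # (5550 + 450) / 100000
        assert total.overall_prev_pct == pytest.approx(10.0)

    def test_empty_cohort_all_zero(self):
        persons = pd.DataFrame({"status": [], "regimen": [], "region": []})
        summary = pp.true_summary(persons)
        assert (summary[["n", "treated_prev_pct", "overall_prev_pct"]] == 0).all().all()

    def test_regional_counts_sum_to_total(self, registry):
        cfg = pp.CohortConfig(
            n_pop=30_000, regions=(("North", 0.35), ("Centre", 0.4), ("South", 0.25)),
            mode="stochastic", seed=7,
        )
        persons = pp.generate_cohort(cfg, registry)
        summary = pp.true_summary(persons).set_index("region")
        regions = summary.drop(index="TOTAL")
        for column in ["n", "n_t2dm_nad", "n_t2dm_insulin", "n_t2dm_undiagnosed", "n_t1dm"]:
            assert regions[column].sum() == summary.loc["TOTAL", column]


def _recover(cfg, registry):
    persons = pp.generate_cohort(cfg, registry)
    records = pp.simulate_dispensing(persons, registry, cfg)
    population = pp.population_table(cfg, persons)
    consumption = pp.aggregate_consumption(records, registry, population, level=3)
    params = pp.matched_model_params(cfg, persons)
    est = pp.run_model(consumption, population, params, scopes=["TOTAL"]).iloc[0]
    truth = pp.true_summary(persons).set_index("region").loc["TOTAL"]
    return est, truth


class TestParameterRecovery:
    def test_deterministic_mode_recovers_exactly(self, config, registry):
        """With every generative assumption matching the model, the full
        pipeline returns the cohort's true prevalences to float precision."""
        est, truth = _recover(config, registry)
        assert math.isclose(est.prev_treated_pct, truth.treated_prev_pct, rel_tol=1e-12)
        assert math.isclose(est.prev_overall_pct, truth.overall_prev_pct, rel_tol=1e-12)

    def test_stochastic_mode_recovers_within_monte_carlo_error(self, registry):
        cfg = pp.CohortConfig(n_pop=50_000, mode="stochastic", seed=2)
        est, truth = _recover(cfg, registry)
        assert est.prev_treated_pct == pytest.approx(truth.treated_prev_pct, abs=0.1)

    def test_misspecified_adherence_biases_in_published_direction(self, config, registry):
        """Assuming higher adherence than generated biases prevalence down,
        lower biases it up — the direction the scenario table shows."""
        persons = pp.generate_cohort(config, registry)
        records = pp.simulate_dispensing(persons, registry, config)
        population = pp.population_table(cfg := config, persons)
        consumption = pp.aggregate_consumption(records, registry, population, level=3)
        matched = pp.matched_model_params(cfg, persons)
        truth = pp.true_summary(persons).set_index("region").loc["TOTAL"]
        over = pp.run_model(
            consumption, population, matched.replace(adherence_nad=0.9),
            scopes=["TOTAL"],
        ).iloc[0]
        under = pp.run_model(
            consumption, population, matched.replace(adherence_nad=0.4),
            scopes=["TOTAL"],
        ).iloc[0]
        assert over.prev_treated_pct < truth.treated_prev_pct < under.prev_treated_pct

    def test_matched_params_from_config_close_to_realised(self, config, registry):
        persons = pp.generate_cohort(config, registry)
        from_config = pp.matched_model_params(config)
        from_cohort = pp.matched_model_params(config, persons)
        assert from_config.effective_w == pytest.approx(from_cohort.effective_w, abs=1e-3)
        assert from_config.insulin_t2dm_fraction == pytest.approx(
            from_cohort.insulin_t2dm_fraction, abs=1e-3
        )
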