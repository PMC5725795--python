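"""Scenario DGPs: exposure, GA shifts, BW generation, cohort assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sga_mediation import (
    SCENARIOS,
    BWMeanModel,
    ErrorModel,
    GADistribution,
    ScenarioSpec,
    Variant,
    get_scenario,
    make_default_ga_distribution,
    mean_bw,
    simulate_cohort,
)
from sga_mediation.ga_reference import sga_threshold
from sga_mediation.scenarios import (
    LBW_CUTOFF,
    apply_ga_shifts,
    generate_bw,
    load_cohort,
    sample_base_ga,
    sample_confounder,
    sample_exposure,
    save_cohort,
)


class TestScenarioRegistry:
    def test_all_eight_scenarios_present(self):
        assert list(SCENARIOS) == [
            "basic1", "basic2", "basic3", "basic4",
            "conf1", "conf2", "conf3", "conf4",
        ]

    def test_basic_scenarios_have_no_confounder_and_symmetric_exposure(self):
        for name in ("basic1", "basic2", "basic3", "basic4"):
            spec = SCENARIOS[name]
            assert not spec.has_confounder
            assert spec.p_exposure_given_v == (0.5, 0.5)

    def test_confounding_edge_sets_match_study_design(self):
        assert SCENARIOS["conf1"].edges == {"V->ICS", "V->GA", "ICS->GA"}
        assert SCENARIOS["conf2"].edges == {"V->GA", "V->BW", "ICS->GA"}
        assert SCENARIOS["conf3"].edges == {"V->ICS", "V->BW", "ICS->GA"}
        assert SCENARIOS["conf4"].edges == {"V->ICS", "V->GA", "V->BW", "ICS->GA"}

    def test_effect_sizes_implied_by_edges(self):
        assert SCENARIOS["basic2"].ga_shift_ics == -2
        assert SCENARIOS["basic2"].beta_ics == 0.0
        assert SCENARIOS["basic3"].ga_shift_ics == 0
        assert SCENARIOS["basic3"].beta_ics == -100.0
        assert SCENARIOS["conf4"].ga_shift_v == -2
        assert SCENARIOS["conf4"].beta_v == -100.0
        assert SCENARIOS["conf1"].p_exposure_given_v == (0.7, 0.3)

    def test_unknown_scenario_error_lists_valid_names(self):
        with pytest.raises(KeyError, match="basic1"):
            get_scenario("nope")

    def test_unknown_edges_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", frozenset({"BW->GA"}))


class TestSampleConfounder:
    def test_exactly_half_exposed_to_confounder(self):
        v = sample_confounder(20_000)
        assert v.sum() == 10_000
        assert len(v) == 20_000

    def test_two_babies_one_of_each(self):
        assert sample_confounder(2).tolist() == [0, 1]

    def test_odd_sample_size_rejected(self):
        with pytest.raises(ValueError):
            sample_confounder(20_001)


class TestSampleExposure:
    def test_conditional_probability_when_v_causes_exposure(self, rng):
        n = 100_000
        ics = sample_exposure(np.ones(n, dtype=int), SCENARIOS["conf1"], rng)
        assert abs(ics.mean() - 0.7) < 3 * np.sqrt(0.21 / n)

    def test_symmetric_probability_in_basic_scenarios(self, rng):
        n = 100_000
        ics = sample_exposure(np.zeros(n, dtype=int), SCENARIOS["basic2"], rng)
        assert abs(ics.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_certain_exposure_limiting_case(self, rng):
        spec = ScenarioSpec("all-exposed", frozenset(), exposure_probs=(1.0, 1.0))
        ics = sample_exposure(np.array([0, 1] * 50), spec, rng)
        assert (ics == 1).all()


class TestSampleBaseGA:
    def test_empirical_frequencies_match_distribution(self, rng):
        dist = make_default_ga_distribution()
        n = 100_000
        draws = sample_base_ga(n, dist, rng)
        for week, p in zip(dist.weeks, dist.probs):
            observed = (draws == week).mean()
            assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-12

    def test_degenerate_distribution_draws_single_week(self, rng):
        dist = GADistribution.from_mapping({40: 1.0})
        assert (sample_base_ga(1000, dist, rng) == 40).all()

    def test_confounder_halves_share_base_draws(self, rng):
        dist = make_default_ga_distribution()
        v = sample_confounder(10_000)
        draws = sample_base_ga(10_000, dist, rng, v=v)
        np.testing.assert_array_equal(draws[:5000], draws[5000:])

    def test_pairing_requires_half_half_layout(self, rng):
        dist = make_default_ga_distribution()
        with pytest.raises(ValueError):
            sample_base_ga(4, dist, rng, v=np.array([1, 0, 0, 1]))


class TestApplyGAShifts:
    def test_exposure_shift_subtracts_two_weeks(self):
        ga = apply_ga_shifts(np.array([40]), np.array([0]), np.array([1]), SCENARIOS["basic2"])
        assert ga.tolist() == [38]

    def test_shifts_compose_in_conf4(self):
        ga = apply_ga_shifts(np.array([40]), np.array([1]), np.array([1]), SCENARIOS["conf4"])
        assert ga.tolist() == [36]

    def test_identity_without_ga_edges(self):
        base = np.array([26, 35, 43])
        ga = apply_ga_shifts(base, np.array([1, 0, 1]), np.array([1, 1, 0]), SCENARIOS["basic3"])
        np.testing.assert_array_equal(ga, base)

    def test_no_clipping_below_26(self):
        ga = apply_ga_shifts(np.array([26]), np.array([1]), np.array([1]), SCENARIOS["conf4"])
        assert ga.tolist() == [22]


class TestGenerateBW:
    def test_sample_mean_matches_reference_at_28_weeks(self, rng):
        n = 100_000
        model, err = BWMeanModel.linear_default(), ErrorModel.homoskedastic()
        bw = generate_bw(np.full(n, 28), np.zeros(n, int), np.zeros(n, int), model, err, rng)
        assert abs(bw.mean() - 1427.7) < 3 * 333.82 / np.sqrt(n)

    def test_direct_effect_shifts_mean_by_coefficient(self, rng):
        n = 100_000
        model = BWMeanModel.linear_default(beta_ics=-100.0)
        err = ErrorModel.homoskedastic()
        bw = generate_bw(np.full(n, 28), np.ones(n, int), np.zeros(n, int), model, err, rng)
        assert abs(bw.mean() - 1327.7) < 3 * 333.82 / np.sqrt(n)

    def test_vanishing_sd_returns_exact_means(self, rng):
        model = BWMeanModel.linear_default()
        err = ErrorModel.homoskedastic(1e-12)
        ga = np.array([28, 30, 40])
        bw = generate_bw(ga, np.zeros(3, int), np.zeros(3, int), model, err, rng)
        expected = mean_bw(ga, np.zeros(3, int), np.zeros(3, int), model)
        np.testing.assert_allclose(bw, expected, atol=1e-9)


class TestSimulateCohort:
    def test_same_seed_gives_identical_cohorts(self):
        a = simulate_cohort("conf1", n=2000, seed=42)
        b = simulate_cohort("conf1", n=2000, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_cohort("basic1", n=2000, seed=1)
        b = simulate_cohort("basic1", n=2000, seed=2)
        assert not a["bw"].equals(b["bw"])

    def test_lbw_and_sga_are_recomputable_from_ga_and_bw(self, linear_homo):
        cohort = simulate_cohort("conf4", linear_homo, n=20_000, seed=3)
        model = linear_homo.mean_model(SCENARIOS["conf4"].beta_ics, SCENARIOS["conf4"].beta_v)
        err = linear_homo.error_model()
        thresholds = np.array(
            [sga_threshold(g, model, err) for g in cohort["ga"]]
        )
        np.testing.assert_array_equal(cohort["lbw"], (cohort["bw"] < LBW_CUTOFF).astype(int))
        np.testing.assert_array_equal(cohort["sga"], (cohort["bw"] < thresholds).astype(int))

    def test_confounding_cohort_has_exactly_half_v_one(self):
        cohort = simulate_cohort("conf2", n=20_000, seed=4)
        assert cohort["v"].sum() == 10_000

    def test_exposed_ga_shift_is_two_weeks_in_basic2(self):
        cohort = simulate_cohort("basic2", n=50_000, seed=5)
        diff = cohort.loc[cohort.ics == 1, "ga"].mean() - cohort.loc[cohort.ics == 0, "ga"].mean()
        assert diff == pytest.approx(-2.0, abs=0.05)

    @pytest.mark.parametrize("name", ["basic1", "basic3"])
    def test_ga_marginal_identical_across_exposure_without_ga_edge(self, name):
        cohort = simulate_cohort(name, n=50_000, seed=6)
        exposed = cohort.loc[cohort.ics == 1, "ga"]
        unexposed = cohort.loc[cohort.ics == 0, "ga"]
        assert stats.ks_2samp(exposed, unexposed).pvalue > 0.01

    def test_conf3_ga_identical_across_v_strata(self):
        # no V->GA edge and shared base draws: the GA multisets match exactly
        cohort = simulate_cohort("conf3", n=20_000, seed=7)
        # exposure shifts differ per baby, so compare the *base* GA by undoing shifts
        base = cohort["ga"] + 2 * cohort["ics"]
        counts0 = np.bincount(base[cohort.v == 0], minlength=44)
        counts1 = np.bincount(base[cohort.v == 1], minlength=44)
        np.testing.assert_array_equal(counts0, counts1)

    def test_conditional_sga_rate_is_one_tenth_for_reference_babies(self):
        cohort = simulate_cohort("basic2", n=200_000, seed=8)
        ref = cohort[cohort.ics == 0]
        for week, group in ref.groupby("ga"):
            if len(group) < 2000:
                continue
            rate = group["sga"].mean()
            assert abs(rate - 0.10) < 3 * np.sqrt(0.09 / len(group))

    def test_null_scenario_shows_no_exposure_bw_association(self):
        cohort = simulate_cohort("basic1", n=20_000, seed=9)
        exposed = cohort.loc[cohort.ics == 1, "bw"]
        unexposed = cohort.loc[cohort.ics == 0, "bw"]
        diff = exposed.mean() - unexposed.mean()
        se = np.sqrt(exposed.var() / len(exposed) + unexposed.var() / len(unexposed))
        assert abs(diff) < 3 * se

    def test_csv_round_trip(self, tmp_path):
        cohort = simulate_cohort("basic4", n=1000, seed=10)
        path = tmp_path / "cohort.csv"
        save_cohort(cohort, path)
        loaded = load_cohort(path)
        assert list(loaded.columns) == ["v", "ics", "ga", "bw", "lbw", "sga"]
        np.testing.assert_allclose(loaded["bw"], cohort["bw"])

    def test_load_rejects_wrong_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            load_cohort(path)
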