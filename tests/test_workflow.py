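import numpy as np
import pytest

from screentriage.bootstrap import bootstrap_cohorts
from screentriage.errors import ConfigurationError, UndefinedMetricError
from screentriage.workflow import (
    ReaderModel,
    ScenarioOutcome,
    accuracy_increase,
    bootstrap_scenarios,
    predictive_values,
    run_scenario,
    workload_reduction,
)

from conftest import random_visits


@pytest.fixture(scope="module")
def simulated_cohort(fixture_visits):
    """One prevalence-matched cohort of 18,421 visits (105 cancers)."""
    (cohort,) = bootstrap_cohorts(fixture_visits, rate=0.0057, n_iter=1, seed=0)
    return cohort.to_frame(fixture_visits)


class TestWorkloads:
    def test_double_reading_reads_everything_twice(self, simulated_cohort):
        out = run_scenario(simulated_cohort, "bmsp")
        assert out.workload == 36_842
        assert out.n_visits == 18_421

    def test_single_reader_halves_the_workload(self, simulated_cohort):
        out = run_scenario(simulated_cohort, "s1")
        assert out.workload == 18_421

    def test_flagged_review_adds_one_read_per_yellow(self, simulated_cohort):
        out = run_scenario(simulated_cohort, "s2")
        yellow = ((simulated_cohort["ai_score"] > 1.0)
                  & (simulated_cohort["ai_score"] < 30.44)).sum()
        assert out.workload == 18_421 + yellow

    def test_triage_reads_only_yellow_and_red(self, simulated_cohort):
        out = run_scenario(simulated_cohort, "s3")
        read = (simulated_cohort["ai_score"] > 1.0).sum()
        assert out.workload == read


class TestDetection:
    def test_triage_with_flag_perfect_reader_on_fixture(self, fixture_visits):
        out = run_scenario(fixture_visits, "s3")
        assert out.detected_cancers == 100
        assert out.missed_or_interval == 5

    def test_hybrid_flagged_review_detects_all_but_green_misses(self, fixture_visits):
        # 76 red + 24 yellow + 1 green recorded-detected
        out = run_scenario(fixture_visits, "s2")
        assert out.detected_cancers == 101
        assert out.missed_or_interval == 4

    def test_ai_second_reader_is_union_of_human_and_red(self, fixture_visits):
        # recorded human (68) plus AI-red interval/missed (15 + 4)
        out = run_scenario(fixture_visits, "s1")
        assert out.detected_cancers == 87

    def test_double_reading_detects_the_recorded_cancers(self, fixture_visits):
        out = run_scenario(fixture_visits, "bmsp")
        assert out.detected_cancers == 68

    @pytest.mark.parametrize("scenario", ["bmsp", "s1", "s2", "s3"])
    def test_detected_plus_missed_conserved(self, fixture_visits, scenario):
        out = run_scenario(fixture_visits, scenario)
        assert out.detected_cancers + out.missed_or_interval == 105

    def test_observed_reader_variant_of_triage(self, fixture_visits):
        out = run_scenario(fixture_visits, "s3", reader=ReaderModel.observed())
        # red auto-escalation (76) plus recorded recalls among yellow (10)
        assert out.detected_cancers == 86

    def test_unknown_scenario_rejected(self, fixture_visits):
        with pytest.raises(ConfigurationError):
            run_scenario(fixture_visits, "s4")


class TestComparisons:
    def test_identical_outcomes_have_zero_reduction(self, fixture_visits):
        out = run_scenario(fixture_visits, "bmsp")
        assert workload_reduction(out, out) == 0.0

    def test_single_reader_is_half_of_double_reading(self, simulated_cohort):
        s1 = run_scenario(simulated_cohort, "s1")
        bmsp = run_scenario(simulated_cohort, "bmsp")
        assert workload_reduction(s1, bmsp) == pytest.approx(50.0)

    def test_accuracy_increase_of_triage_over_double_reading(self, fixture_visits):
        s3 = run_scenario(fixture_visits, "s3")
        bmsp = run_scenario(fixture_visits, "bmsp")
        assert accuracy_increase(s3, bmsp, 105) == pytest.approx(100 * 32 / 105)
        assert round(accuracy_increase(s3, bmsp, 105), 1) == 30.5

    def test_equal_detection_is_zero_increase(self, fixture_visits):
        out = run_scenario(fixture_visits, "s1")
        assert accuracy_increase(out, out, 105) == 0.0

    def test_flagged_review_dominates_single_reader(self, rng):
        # adding a second reading stage never loses cancers or reads
        for _ in range(5):
            visits = random_visits(rng, n=300)
            s1 = run_scenario(visits, "s1", reader=ReaderModel.flag_perfect())
            s2 = run_scenario(visits, "s2", reader=ReaderModel.flag_perfect())
            assert s2.detected_cancers >= s1.detected_cancers
            assert s2.workload >= s1.workload


class TestPredictiveValues:
    def test_all_recalls_cancers_gives_unit_ppv1(self):
        out = ScenarioOutcome("s3", "flag_perfect", 100, 10, 50, 10, 0,
                              recalls=10, cancers_recalled=10, negatives=90)
        assert predictive_values(out)["ppv1"] == 1.0

    def test_no_cancer_among_negatives_gives_unit_npv(self, fixture_visits):
        visits = fixture_visits.copy()
        visits.loc[visits["is_cancer_visit"], "ai_score"] = 90.0
        out = run_scenario(visits, "s3")
        assert predictive_values(out)["npv"] == 1.0

    def test_zero_recalls_undefined(self):
        out = ScenarioOutcome("s3", "observed", 100, 0, 0, 0, 0,
                              recalls=0, cancers_recalled=0, negatives=100)
        with pytest.raises(UndefinedMetricError):
            predictive_values(out)


class TestBootstrapScenarios:
    def test_closed_form_workload_expectations(self, fixture_visits):
        # E[s2 workload] = N + E[yellow]; E[s3 workload] = E[yellow + red]
        n_iter = 400
        summary = bootstrap_scenarios(fixture_visits, rate=0.0057,
                                      n_iter=n_iter, seed=5)
        p_y = 2616 / 4893
        p_r = 349 / 4893
        n = 18_316
        exp_s2 = 18_421 + n * p_y + 24
        exp_s3 = n * (p_y + p_r) + 100
        sd_y = np.sqrt(n * p_y * (1 - p_y))
        sd_yr = np.sqrt(n * (p_y + p_r) * (1 - p_y - p_r))
        assert abs(summary.loc["s2", "workload_mean"] - exp_s2) \
            <= 3 * sd_y / np.sqrt(n_iter)
        assert abs(summary.loc["s3", "workload_mean"] - exp_s3) \
            <= 3 * sd_yr / np.sqrt(n_iter)

    def test_detection_constant_across_iterations(self, fixture_visits):
        summary = bootstrap_scenarios(fixture_visits, n_iter=50, seed=6)
        assert summary["detected_cancers"].tolist() == [68, 87, 101, 100]
        assert (summary["detected_cancers"]
                + summary["missed_or_interval"]).tolist() == [105] * 4

    def test_reproducible_given_seed(self, fixture_visits):
        a = bootstrap_scenarios(fixture_visits, n_iter=50, seed=8)
        b = bootstrap_scenarios(fixture_visits, n_iter=50, seed=8)
        assert a.equals(b)
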