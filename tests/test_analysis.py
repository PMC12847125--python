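import math

import numpy as np
import pytest

from patchforage.analysis import (
    compare_to_optimal,
    estimate_timing,
    learning_trend,
    mannwhitney,
    summaries_table,
    summarize_trial,
    switch_probability_table,
    switch_records,
)
from patchforage.optimal_solver import OptimalSolver
from patchforage.rollout import TrialEvent, TrialLog, run_trial
from patchforage.synthetic_cohort import (
    CohortDesign,
    PopulationParams,
    generate_study_logs,
)
from patchforage.task_model import (
    EnvLabel,
    EnvironmentConfig,
    LONG_BATTERY,
    MEAN_TIMING,
    SHORT_BATTERY,
)


def manual_log(events, config=None, env_label=EnvLabel.RICH, battery="long",
               duration=50.0):
    return TrialLog(
        subject_id="S00",
        trial_index=1,
        env_label=env_label,
        battery_label=battery,
        battery_duration=duration,
        config=config or EnvironmentConfig.all_rich(),
        events=events,
    )


class TestSummarizeTrial:
    def test_single_area_arithmetic(self):
        log = manual_log([
            TrialEvent(3.0, "move_collect", 0, 1, 8),
            TrialEvent(6.0, "stay_collect", 0, 2, 7),
            TrialEvent(9.5, "stay_collect", 0, 3, 6),
        ])
        s = summarize_trial(log)
        assert s.total_coins == 21
        assert s.boxes_collected == 3
        assert s.boxes_in_first_area == 3
        assert s.avg_coins_per_box == pytest.approx(7.0)
        assert s.n_unique_areas == 1
        assert s.avg_box_collection_time == pytest.approx((3.0 + 3.5) / 2)

    def test_single_collection_has_no_interval(self):
        log = manual_log([TrialEvent(3.0, "move_collect", 0, 1, 8)])
        assert math.isnan(summarize_trial(log).avg_box_collection_time)

    def test_identity_holds_on_generated_logs(self, small_noisy_cohort):
        logs, _ = small_noisy_cohort
        table = summaries_table(logs)
        product = table["avg_coins_per_box"] * table["boxes_collected"]
        assert np.allclose(product, table["total_coins"])
        assert table["boxes_in_first_area"].le(table["boxes_collected"]).all()
        assert table["n_unique_areas"].between(1, 4).all()

    def test_optimal_rich_trials_have_integer_dvs(self, mean_solver, rng):
        log = run_trial(
            mean_solver.as_policy(), EnvironmentConfig.all_rich(),
            LONG_BATTERY, MEAN_TIMING, rng,
        )
        s = summarize_trial(log)
        assert float(s.total_coins).is_integer()
        assert float(s.avg_coins_per_box * s.boxes_collected).is_integer()

    def test_malformed_log_rejected(self):
        log = manual_log([TrialEvent(3.0, "move_collect", 0, 1, 3)])
        with pytest.raises(ValueError, match="schedule"):
            summarize_trial(log)


class TestEstimateTiming:
    def test_exact_recovery_from_noiseless_logs(self, small_noiseless_cohort):
        """With optimal play and no movement jitter every within-area interval
        is exactly T1 and every switch interval exactly T2."""
        logs, cohort = small_noiseless_cohort
        by_subject = {}
        for log in logs:
            by_subject.setdefault(log.subject_id, []).append(log)
        for sid, subject_logs in by_subject.items():
            est = estimate_timing(subject_logs)
            truth = cohort.subjects[sid].timing
            assert est.t1_hat == pytest.approx(truth.t1, abs=1e-9)
            assert est.t2_hat == pytest.approx(truth.t2, abs=1e-9)
            assert est.n_t1 > 0 and est.n_t2 > 0

    def test_insufficient_intervals_rejected(self):
        log = manual_log([TrialEvent(3.0, "move_collect", 0, 1, 8)])
        with pytest.raises(ValueError, match="interval"):
            estimate_timing([log])


class TestSwitchRecords:
    def test_final_event_censored(self, mean_solver, rng):
        log = run_trial(
            mean_solver.as_policy(), EnvironmentConfig.all_rich(),
            SHORT_BATTERY, MEAN_TIMING, rng,
        )
        records = switch_records([log])
        assert len(records) == len(log.events) - 1

    def test_fifth_box_always_left(self, small_noisy_cohort):
        logs, _ = small_noisy_cohort
        table = switch_probability_table(logs)
        fifth = table[table["box_ordinal"] == 5]
        assert not fifth.empty
        assert (fifth["p_leave"] == 1.0).all()

    def test_rich_env_rows_always_resolved_and_rich(self, small_noisy_cohort):
        logs, _ = small_noisy_cohort
        records = switch_records(logs)
        rich_env = records[records["env_label"] == "rich_env"]
        assert rich_env["uncertainty_resolved"].all()
        assert (rich_env["area_richness"] == "rich").all()

    def test_at_most_five_condition_cells(self, small_noisy_cohort):
        logs, _ = small_noisy_cohort
        records = switch_records(logs)
        cells = records.groupby(
            ["env_label", "area_richness", "uncertainty_resolved"]
        ).size()
        assert len(cells) <= 5

    def test_resolution_flag_tracks_belief_replay(self):
        """In a mixed trial the flag flips exactly when two same-type areas
        have been sampled."""
        config = EnvironmentConfig.mixed([0, 1])
        log = manual_log(
            [
                TrialEvent(3.4, "move_collect", 0, 1, 8),   # rich revealed
                TrialEvent(9.5, "move_collect", 2, 1, 5),   # poor revealed
                TrialEvent(15.6, "move_collect", 1, 1, 8),  # second rich: resolved
                TrialEvent(19.0, "stay_collect", 1, 2, 7),
            ],
            config=config,
            env_label=EnvLabel.MIXED,
        )
        records = switch_records([log])
        assert records["uncertainty_resolved"].tolist() == [False, False, True]

    def test_optimal_agent_leaves_poor_first_areas_earlier(self, mean_solver):
        """Mirrors the directional pattern: under the optimal policy in mixed
        trials, a revealed-poor area is left with higher probability than a
        revealed-rich one at the same box ordinal."""
        from patchforage.belief import KnowledgeState, consistent_configs

        rng = np.random.default_rng(0)
        logs = []
        for battery in (SHORT_BATTERY, LONG_BATTERY):
            for config, _ in consistent_configs(
                KnowledgeState.initial(EnvLabel.MIXED)
            ):
                logs.append(run_trial(
                    mean_solver.as_policy(), config, battery, MEAN_TIMING, rng,
                ))
        records = switch_records(logs)
        first_box = records[records["box_ordinal"] == 1]
        p_poor = first_box[first_box["area_richness"] == "poor"]["left_after"].mean()
        p_rich = first_box[first_box["area_richness"] == "rich"]["left_after"].mean()
        assert p_poor > p_rich


class TestMannWhitney:
    def test_identical_samples_convention(self):
        u, p = mannwhitney([3, 3, 3], [3, 3, 3])
        assert p == 1.0

    def test_shifted_samples_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        _, p = mannwhitney(x, y)
        assert p < 1e-6

    def test_small_samples_use_exact_null(self):
        # exact two-sided p for fully separated samples of 3 vs 3: 2/20
        _, p = mannwhitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)


class TestCompareToOptimal:
    def test_matched_noiseless_cohort_shows_no_deficit(self, small_noiseless_cohort):
        """Noise-free synthetic subjects ARE optimal agents, so no condition
        cell may differ significantly from the per-subject optimal reference."""
        logs, cohort = small_noiseless_cohort
        agent = summaries_table(logs)
        reference_logs = []
        for log in logs:
            params = cohort.subjects[log.subject_id]
            solver = OptimalSolver(params.timing)
            from patchforage.task_model import BatteryCondition

            reference_logs.append(run_trial(
                solver.as_policy(), log.config,
                BatteryCondition.from_label(log.battery_label),
                params.timing, np.random.default_rng(0),
                subject_id=log.subject_id, trial_index=log.trial_index,
            ))
        optimal = summaries_table(reference_logs)
        result = compare_to_optimal(
            agent, optimal, "total_coins", ["battery_label", "env_label"]
        )
        assert (result["p_value"] > 0.05).all()

    def test_noisy_cohort_shows_long_battery_deficit(self, small_noisy_cohort,
                                                     mean_solver):
        logs, _ = small_noisy_cohort
        agent = summaries_table(logs)
        agent = agent[(agent["battery_label"] == "long")
                      & (agent["env_label"] == "mixed_env")]
        rng = np.random.default_rng(3)
        from patchforage.task_model import sample_environment

        optimal_logs = [
            run_trial(
                mean_solver.as_policy(),
                sample_environment(EnvLabel.MIXED, rng),
                LONG_BATTERY, MEAN_TIMING, rng, trial_index=i,
            )
            for i in range(80)
        ]
        optimal = summaries_table(optimal_logs)
        result = compare_to_optimal(
            agent, optimal, "total_coins", ["battery_label", "env_label"]
        )
        row = result.iloc[0]
        assert row["direction"] == "agent_lower"
        assert row["p_value"] < 0.05

    def test_empty_cell_rejected(self, small_noisy_cohort):
        logs, _ = small_noisy_cohort
        agent = summaries_table(logs)
        optimal = agent[agent["battery_label"] == "long"]
        with pytest.raises(ValueError, match="cell"):
            compare_to_optimal(
                agent, optimal, "total_coins", ["battery_label", "env_label"]
            )


class TestLearningTrend:
    def test_speedup_cohort_improves_box_counts(self):
        design = CohortDesign(n_subjects=5, trials_per_block=10)
        population = PopulationParams(
            beta=0.0, interval_jitter_sd=0.0, timing_speedup_per_trial=0.97
        )
        logs, _ = generate_study_logs(design, population, seed=31)
        table = summaries_table(logs)
        fit = learning_trend(table, "boxes_collected")
        assert fit.slope > 0
        assert fit.p_value < 0.05

    def test_stationary_noiseless_cohort_is_flat(self, small_noiseless_cohort):
        """Without learning modifiers the trend is materially flat: the slope
        is a tiny fraction of the mean level (deterministic agents leave so
        little residual variance that p-values alone are not informative)."""
        logs, _ = small_noiseless_cohort
        table = summaries_table(logs)
        fit = learning_trend(table, "boxes_collected")
        mean_level = table["boxes_collected"].mean()
        assert abs(fit.slope) * 40 < 0.25 * mean_level

    def test_constant_variable_has_zero_r_squared(self):
        import pandas as pd

        table = pd.DataFrame({
            "trial_index": list(range(1, 11)),
            "value": [4.0] * 10,
        })
        fit = learning_trend(table, "value")
        assert fit.r_squared == 0.0 and fit.slope == 0.0

    def test_too_few_indices_rejected(self):
        import pandas as pd

        table = pd.DataFrame({"trial_index": [1, 2], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="three"):
            learning_trend(table, "value")
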