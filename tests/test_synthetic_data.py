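import numpy as np
import pytest

from mostrip.stability import compute_step_mos
from mostrip.gait_events import StepRecord
from mostrip.synthetic_data import (
    CONDITIONS,
    Condition,
    ScheduleInfeasibleError,
    SimulationParams,
    generate_cohort,
    generate_schedule,
    generate_trial,
    schedule_for_condition,
)


class TestSchedule:
    def test_counts_and_sides(self):
        sched = generate_schedule(4, 3, 200, seed=7)
        assert len(sched.entries) == 7
        assert sched.n_right == 4 and sched.n_left == 3

    def test_empty(self):
        assert generate_schedule(0, 0, 100, seed=0).entries == ()

    def test_deterministic(self):
        a = generate_schedule(4, 3, 200, seed=42)
        b = generate_schedule(4, 3, 200, seed=42)
        assert a.entries == b.entries

    @pytest.mark.parametrize("seed", range(8))
    def test_spacing_and_parity(self, seed):
        sched = generate_schedule(4, 3, 60, seed=seed)
        ordinals = [o for o, _ in sched.entries]
        assert all(b - a >= 6 for a, b in zip(ordinals, ordinals[1:]))
        for o, side in sched.entries:
            assert side == ("right" if o % 2 == 0 else "left")

    def test_infeasible_raises(self):
        with pytest.raises(ScheduleInfeasibleError, match="spacing"):
            generate_schedule(4, 3, 20, seed=0)

    def test_series_schemes(self):
        right = schedule_for_condition(Condition("slow", "series_right", "none"), 60, seed=0)
        left = schedule_for_condition(Condition("slow", "series_left", "none"), 60, seed=0)
        assert right.n_right == 7 and right.n_left == 0
        assert left.n_left == 7 and left.n_right == 0


class TestCondition:
    def test_grid_has_eight_cells(self):
        assert len(CONDITIONS) == 8
        assert len({c.name for c in CONDITIONS}) == 8

    def test_invalid_combination_rejected(self):
        with pytest.raises(ValueError):
            Condition("fast", "series_right", "none")
        with pytest.raises(ValueError):
            Condition("slow", "none", "buzzer")


class TestTrial:
    def test_unperturbed_mos_all_positive(self, unperturbed_trial):
        _, _, _, truth = unperturbed_trial
        assert (truth.steps["mos_mm"] > 0).all()
        assert (truth.steps["label"] == "baseline").all()

    def test_seven_perturbed_steps(self, perturbed_trial):
        _, _, _, truth = perturbed_trial
        assert (truth.steps["label"] == "perturbed").sum() == 7
        assert len(truth.perturbation_frames) == 7

    def test_noise_free_self_consistency(self, perturbed_trial):
        """The stability module reproduces ground-truth MoS to <= 1e-6 m."""
        _, _, rec, truth = perturbed_trial
        steps = [
            StepRecord(r.ordinal, r.side, r.hs_frame, r.label)
            for r in truth.steps.itertuples()
        ]
        records = compute_step_mos(rec, steps)
        err_mm = np.abs(
            np.array([m.mos for m in records]) - truth.steps["mos_mm"].to_numpy()
        )
        assert err_mm.max() <= 1e-3  # 1e-6 m

    def test_ground_truth_events_ordered_and_alternating(self, perturbed_trial):
        _, _, _, truth = perturbed_trial
        ev = truth.events
        assert (np.diff(ev["frame"]) > 0).all() or (
            np.diff(ev["frame"]) >= 0
        ).all()  # sorted
        for side in ("left", "right"):
            kinds = ev.loc[ev["side"] == side, "kind"].tolist()
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_bit_identical_determinism(self, noise_free_params):
        cond = Condition("slow", "random", "basket")
        sched = schedule_for_condition(cond, 60, seed=9)
        a, ta = generate_trial(noise_free_params, cond, sched, 25.0, seed=4)
        b, tb = generate_trial(noise_free_params, cond, sched, 25.0, seed=4)
        for name in a.markers:
            np.testing.assert_array_equal(a.markers[name], b.markers[name])
        assert ta.steps.equals(tb.steps)

    def test_scheme_schedule_consistency_enforced(self, noise_free_params):
        sched = schedule_for_condition(Condition("slow", "random", "buzzer"), 60, seed=0)
        with pytest.raises(ValueError, match="empty schedule"):
            generate_trial(
                noise_free_params, Condition("slow", "none", "none"), sched, 23.6, seed=0
            )

    def test_block_longer_than_swing_rejected(self):
        with pytest.raises(ValueError, match="block_duration"):
            SimulationParams(block_duration=0.6)

    def test_nonpositive_speed_rejected(self, noise_free_params):
        cond = Condition("slow", "none", "none")
        sched = schedule_for_condition(cond, 60, seed=0)
        with pytest.raises(ValueError, match="speed"):
            generate_trial(noise_free_params, cond, sched, 23.6, seed=0, belt_speed=0.0)

    def test_harness_load_peaks_injected(self, noise_free_params):
        cond = Condition("slow", "none", "none")
        sched = schedule_for_condition(cond, 60, seed=0)
        rec, _ = generate_trial(
            noise_free_params, cond, sched, 23.6, seed=0,
            load_peaks=((100, 35.0, 2), (300, 50.0, 5)),
        )
        assert rec.harness_load[100] == 35.0
        assert (rec.harness_load[300:305] == 50.0).all()
        assert rec.harness_load.max() == 50.0


class TestCohort:
    def test_risk_scores_within_range(self):
        params = SimulationParams(n_participants=19)
        cohort = generate_cohort(params, conditions=())
        r = cohort.participants["risk_score"]
        assert len(r) == 19
        assert ((r >= params.risk_min) & (r <= params.risk_max)).all()

    def test_risk_mean_monte_carlo(self):
        """Sample mean of 1000 truncated-normal risk scores near 23.6."""
        params = SimulationParams(n_participants=1000, seed=123)
        cohort = generate_cohort(params, conditions=())
        assert abs(cohort.participants["risk_score"].mean() - 23.6) < 0.5

    def test_degenerate_fast_factor(self):
        params = SimulationParams(n_participants=5, fast_factor=1.0)
        cohort = generate_cohort(params, conditions=())
        np.testing.assert_allclose(
            cohort.participants["slow_speed_mps"], cohort.participants["fast_speed_mps"]
        )

    def test_cohort_reproducible(self):
        params = SimulationParams(n_participants=3, seed=7, marker_noise_sd=0.0)
        conds = (Condition("slow", "series_right", "none"),)
        a = generate_cohort(params, conditions=conds)
        b = generate_cohort(params, conditions=conds)
        assert a.participants.equals(b.participants)
        for (ia, ca, ra, ta), (ib, cb, rb, tb) in zip(a.trials, b.trials):
            assert ia == ib and ca == cb
            np.testing.assert_array_equal(ra.markers["com"], rb.markers["com"])
            assert ta.steps.equals(tb.steps)
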