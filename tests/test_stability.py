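import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mostrip.gait_events import StepRecord
from mostrip.recording import TrialRecording
from mostrip.stability import (
    compute_step_mos,
    detect_fall_events,
    effective_leg_length,
    extrapolated_com,
    margin_of_stability,
)

finite = st.floats(-10, 10, allow_nan=False)


class TestEffectiveLegLength:
    def test_unit_axis(self):
        assert effective_leg_length((0, 0, 1), (0, 0, 0)) == 1.0

    def test_pythagoras(self):
        assert effective_leg_length((0.3, 0, 0.9), (0, 0, 0)) == pytest.approx(
            np.sqrt(0.3**2 + 0.9**2), abs=1e-12
        )

    def test_degenerate_markers_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            effective_leg_length((0.0, 0.0, 1e-9), (0.0, 0.0, 0.0))


class TestExtrapolatedCom:
    def test_zero_relative_velocity(self):
        assert extrapolated_com(0.42, -0.57, -0.57, 0.95) == pytest.approx(0.42)

    def test_hand_oracle_sqrt_ten(self):
        # sqrt(g/l) = sqrt(9.81/0.981) = sqrt(10); 0.316228/sqrt(10) = 0.1
        x = extrapolated_com(0.0, 0.316228, 0.0, 0.981, g=9.81)
        assert x == pytest.approx(0.1, abs=1e-6)

    def test_linearity_in_relative_velocity(self):
        base = extrapolated_com(0.0, 0.2, -0.1, 1.0)
        double = extrapolated_com(0.0, 0.5, -0.1, 1.0)
        assert double == pytest.approx(2 * base, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            extrapolated_com(0, 0, 0, -1.0)
        with pytest.raises(ValueError):
            extrapolated_com(0, 0, 0, 1.0, g=0)

    @given(finite, finite, st.floats(0.5, 1.5), st.floats(-1, 1))
    @settings(max_examples=200, deadline=None)
    def test_galilean_invariance(self, vel, belt, leg, shift):
        a = extrapolated_com(0.1, vel, belt, leg)
        b = extrapolated_com(0.1, vel + shift, belt + shift, leg)
        assert a == pytest.approx(b, abs=1e-9)


class TestMarginOfStability:
    def test_coincidence_zero(self):
        assert margin_of_stability(0.5, 0.5) == 0.0

    def test_direct_subtraction(self):
        assert margin_of_stability(0.50, 0.60) == pytest.approx(-100.0)

    @given(finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        assert margin_of_stability(a, b) == pytest.approx(
            -margin_of_stability(b, a), abs=1e-9
        )

    @given(st.floats(-0.2, 0.2), st.floats(0.6, 1.2), st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_relative_velocity(self, vrel, leg, dv):
        xa = extrapolated_com(0.0, vrel, 0.0, leg)
        xb = extrapolated_com(0.0, vrel + dv, 0.0, leg)
        assert margin_of_stability(0.3, xb) < margin_of_stability(0.3, xa)


def _steps_from_truth(truth):
    return [
        StepRecord(r.ordinal, r.side, r.hs_frame, r.label)
        for r in truth.steps.itertuples()
    ]


class TestComputeStepMos:
    def test_unperturbed_matches_ground_truth(self, unperturbed_trial):
        _, _, rec, truth = unperturbed_trial
        records = compute_step_mos(rec, _steps_from_truth(truth))
        mos = np.array([m.mos for m in records])
        assert (mos > 0).all()
        np.testing.assert_allclose(mos, truth.steps["mos_mm"], atol=1e-3)

    def test_perturbed_steps_negative(self, perturbed_trial):
        _, _, rec, truth = perturbed_trial
        records = compute_step_mos(rec, _steps_from_truth(truth))
        perturbed = [m.mos for m in records if m.label == "perturbed"]
        assert len(perturbed) == 7
        assert all(m < 0 for m in perturbed)

    def test_static_limit(self):
        """Belt at rest and static CoM over the boundary gives MoS = 0."""
        n = 32
        boundary = 0.25
        com = np.tile([boundary, 0.0, 0.9], (n, 1))
        markers = {
            "com": com,
            "pelvis": com,
            "l_heel": np.tile([0.07, 0.1, 0.0], (n, 1)),
            "r_heel": np.tile([0.07, -0.1, 0.0], (n, 1)),
            "l_toe": np.tile([boundary, 0.1, 0.0], (n, 1)),
            "r_toe": np.tile([boundary, -0.1, 0.0], (n, 1)),
        }
        rec = TrialRecording(markers, np.zeros(n), np.zeros(n), 100.0)
        (record,) = compute_step_mos(rec, [StepRecord(0, "left", 16)])
        assert record.mos == pytest.approx(0.0, abs=1e-9)

    def test_frame_translation_invariance(self, perturbed_trial):
        _, _, rec, truth = perturbed_trial
        steps = _steps_from_truth(truth)
        base = [m.mos for m in compute_step_mos(rec, steps)]
        shifted = rec.copy()
        for name in shifted.markers:
            shifted.markers[name] = shifted.markers[name] + np.array([5.0, 0.0, 0.0])
        moved = [m.mos for m in compute_step_mos(shifted, steps)]
        np.testing.assert_allclose(moved, base, atol=1e-6)

    def test_missing_frame_flags_invalid(self, unperturbed_trial):
        _, _, rec, truth = unperturbed_trial
        rec = rec.copy()
        steps = _steps_from_truth(truth)
        rec.markers["com"][steps[3].hs_frame] = np.nan
        records = compute_step_mos(rec, steps)
        assert not records[3].valid
        assert all(r.valid for i, r in enumerate(records) if i != 3)

    def test_missing_channel_raises(self, unperturbed_trial):
        _, _, rec, _ = unperturbed_trial
        rec = rec.copy()
        del rec.markers["l_toe"]
        with pytest.raises(KeyError, match="l_toe"):
            compute_step_mos(rec, [StepRecord(0, "left", 150)])


class TestFallEvents:
    def test_zero_load_no_episodes(self):
        assert detect_fall_events(np.zeros(1000)) == []

    def test_single_peak(self):
        load = np.zeros(200)
        load[50:52] = 35.0
        (ep,) = detect_fall_events(load)
        assert (ep.start_frame, ep.end_frame, ep.peak_load) == (50, 51, 35.0)
        assert ep.duration == 2

    def test_nine_disjoint_peaks(self):
        load = np.zeros(1000)
        for k in range(9):
            load[k * 100 + 10 : k * 100 + 13] = 40.0 + k
        episodes = detect_fall_events(load)
        assert len(episodes) == 9
        assert [e.peak_load for e in episodes] == [40.0 + k for k in range(9)]

    def test_strict_inequality_at_threshold(self):
        load = np.full(50, 30.0)  # exactly 30 %BW is not "more than 30%"
        assert detect_fall_events(load, threshold=0.30) == []
        load[10] = 30.0001
        assert len(detect_fall_events(load, threshold=0.30)) == 1
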