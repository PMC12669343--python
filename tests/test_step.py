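"""STEP controller mechanics: CWIR bookkeeping, boundary, estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stepcal.step as step_mod
from stepcal import (IntensityScale, StepConfig, run_step_calibration,
                     sequence_weight, simulated_responder)
from oracles import brute_force_threshold
from stepcal.step import (CalibrationState, EstimationError,
                          adjust_intensity, binomial_boundary_test,
                          estimate_run_threshold, init_run_state,
                          update_boundary, update_cwir, update_step_size)


def make_state(**overrides) -> CalibrationState:
    config = overrides.pop("config", StepConfig())
    state = init_run_state(config)
    for k, v in overrides.items():
        setattr(state, k, v)
    return state


class TestInitAndWeights:
    def test_isi_and_contrast_initialisation(self):
        s = init_run_state(StepConfig())
        assert s.current_intensity == 200.0 and s.boundary == 200.0
        assert s.current_step == 32.0 and s.history == []
        assert s.cwir_current == 0 and s.sequences == []
        c = init_run_state(StepConfig.contrast_experiment())
        assert c.current_intensity == 1.0 and c.boundary == 1.0

    @pytest.mark.parametrize("k, w", [(0, 0), (1, 1), (2, 3), (3, 6), (10, 55)])
    def test_triangular_sequence_weight(self, k, w):
        assert sequence_weight(k) == w

    def test_negative_streak_rejected(self):
        with pytest.raises(ValueError):
            sequence_weight(-1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StepConfig(min_step=40, initial_step=32)
        with pytest.raises(ValueError):
            StepConfig(alpha_base=1.5)
        with pytest.raises(ValueError):
            IntensityScale(10, 5)


class TestCwirBookkeeping:
    def test_incorrect_extends_streak(self):
        s = make_state()
        for _ in range(3):
            update_cwir(s, correct=False, intensity=40.0)
        assert s.cwir_current == 3
        assert s.cwir_total == 6

    def test_correct_closes_streak_with_mean_and_weight(self):
        s = make_state()
        update_cwir(s, False, 40.0)
        update_cwir(s, False, 44.0)
        update_cwir(s, False, 48.0)
        update_cwir(s, True, 52.0)
        assert s.cwir_current == 0
        assert len(s.sequences) == 1
        assert s.sequences[0].length == 3
        assert s.sequences[0].weight == 6
        assert s.sequences[0].mean_intensity == pytest.approx(44.0)

    def test_correct_with_no_open_streak_appends_nothing(self):
        s = make_state()
        update_cwir(s, True, 40.0)
        assert s.sequences == [] and s.cwir_current == 0


class TestAdjustIntensity:
    def test_correct_decreases(self):
        s = make_state(current_intensity=100.0)
        adjust_intensity(s, correct=True, seen=False)
        assert s.current_intensity == 68.0

    def test_incorrect_unseen_increases(self):
        s = make_state(current_intensity=100.0)
        adjust_intensity(s, correct=False, seen=False)
        assert s.current_intensity == 132.0

    def test_incorrect_seen_exempt_before_min_step(self):
        s = make_state(current_intensity=100.0)
        assert not s.min_step_reached
        adjust_intensity(s, correct=False, seen=True)
        assert s.current_intensity == 100.0

    def test_incorrect_seen_increases_after_min_step(self):
        s = make_state(current_intensity=100.0, min_step_reached=True)
        adjust_intensity(s, correct=False, seen=True)
        assert s.current_intensity == 132.0

    def test_clamped_to_boundary_and_minimum(self):
        s = make_state(current_intensity=100.0, boundary=120.0)
        adjust_intensity(s, correct=False, seen=False)
        assert s.current_intensity == 120.0
        s = make_state(current_intensity=10.0)
        adjust_intensity(s, correct=True, seen=False)
        assert s.current_intensity == 0.0

    def test_quantised_scale_snaps_ties_downward(self):
        scale = IntensityScale(0, 200, quantum=8.0)
        assert scale.snap(12.0) == 8.0   # exact midpoint -> lower grid point
        assert scale.snap(12.1) == 16.0
        assert scale.snap(11.9) == 8.0


class TestStepSize:
    def test_decrement_and_floor(self):
        s = make_state()
        update_step_size(s, reversal_occurred=True)
        assert s.current_step == 28.0
        s.current_step = 6.0
        update_step_size(s, True)
        assert s.current_step == 4.0 and s.min_step_reached
        update_step_size(s, True)
        assert s.current_step == 4.0

    def test_no_trigger_no_change(self):
        s = make_state()
        update_step_size(s, reversal_occurred=False)
        assert s.current_step == 32.0

    def test_per_trial_trigger(self):
        s = make_state(config=StepConfig(step_decrease_trigger="per_trial"))
        update_step_size(s, reversal_occurred=False)
        assert s.current_step == 28.0


def _state_with_log(correct_flags, intensities, seen_flags=None,
                    current=None, boundary=None, config=None):
    from stepcal.step import TrialRecord
    s = make_state(config=config or StepConfig())
    seen_flags = seen_flags or [False] * len(correct_flags)
    for i, (c, x, sn) in enumerate(zip(correct_flags, intensities, seen_flags)):
        s.history.append(TrialRecord(i, x, c, sn, 32.0, s.boundary, 0))
    if current is not None:
        s.current_intensity = current
    if boundary is not None:
        s.boundary = boundary
    return s


class TestBoundary:
    def test_all_correct_is_significant(self):
        s = _state_with_log([True] * 10, [100.0] * 10, current=90.0)
        p, alpha, sig = binomial_boundary_test(s)
        assert p == pytest.approx(2 ** -10)
        assert alpha == pytest.approx(0.05)
        assert sig

    def test_half_correct_not_significant(self):
        s = _state_with_log([True] * 5 + [False] * 5, [100.0] * 10,
                            current=90.0)
        # the 5 incorrect trials extend the CWIR total; rebuild without
        s.open_sequence = []
        p, alpha, sig = binomial_boundary_test(s)
        assert p == pytest.approx(0.623, abs=0.001)
        assert not sig

    def test_alpha_shrinks_with_cumulative_weight(self):
        s = make_state()
        for _ in range(19):
            pass
        # cwir_total = 19 via one streak of length 19? weight = 190; instead
        # build streaks totalling weight 19: lengths 3 (6) + 3 (6) + 3 (6) + 1
        for length in (3, 3, 3, 1):
            for _ in range(length):
                update_cwir(s, False, 50.0)
            update_cwir(s, True, 50.0)
        assert s.cwir_total == 19
        _, alpha, _ = binomial_boundary_test(s)
        assert alpha == pytest.approx(0.05 / 20)

    @pytest.mark.parametrize("seen_ratio, expected",
                             [(0.0, 200.0), (1.0, 100.0), (0.5, 150.0)])
    def test_update_interpolates_by_seen_ratio(self, seen_ratio, expected):
        n = 10
        n_seen = int(round(seen_ratio * n))
        seen = [True] * n_seen + [False] * (n - n_seen)
        s = _state_with_log([True] * n, [150.0] * n, seen_flags=seen,
                            current=100.0, boundary=200.0)
        update_boundary(s)
        assert s.boundary == pytest.approx(expected)

    def test_no_subjective_variant_uses_half_weight(self):
        cfg = StepConfig(use_subjective=False)
        s = _state_with_log([True] * 10, [150.0] * 10,
                            seen_flags=[True] * 10, current=100.0,
                            boundary=200.0, config=cfg)
        update_boundary(s)
        assert s.boundary == pytest.approx(150.0)


class TestEstimator:
    def test_single_sequence_returns_its_mean(self):
        s = make_state()
        update_cwir(s, False, 40.0)
        update_cwir(s, True, 40.0)
        assert estimate_run_threshold(s) == pytest.approx(40.0)

    def test_hand_computed_weighted_average(self):
        s = make_state()
        for x in (40.0, 44.0):
            update_cwir(s, False, x)
        update_cwir(s, True, 0.0)
        update_cwir(s, False, 36.0)
        update_cwir(s, True, 0.0)
        assert estimate_run_threshold(s) == pytest.approx((3 * 42 + 1 * 36) / 4)

    def test_open_trailing_sequence_is_included(self):
        s = make_state()
        update_cwir(s, False, 30.0)  # never closed
        assert estimate_run_threshold(s) == pytest.approx(30.0)

    def test_no_incorrect_trials_raises(self):
        with pytest.raises(EstimationError):
            estimate_run_threshold(make_state())

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(1, 60))
        correct = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        intensities = data.draw(st.lists(
            st.floats(0, 200, allow_nan=False), min_size=n, max_size=n))
        s = make_state()
        for c, x in zip(correct, intensities):
            update_cwir(s, c, x)
        if all(correct):
            with pytest.raises(EstimationError):
                estimate_run_threshold(s)
            return
        expected = brute_force_threshold(correct, intensities)
        assert estimate_run_threshold(s) == pytest.approx(expected, rel=1e-12)


class TestFullCalibration:
    def test_final_is_mean_of_run_thresholds(self, canonical_participant):
        res = run_step_calibration(
            simulated_responder(canonical_participant,
                                np.random.default_rng(0)))
        assert res.final_threshold == pytest.approx(
            np.mean(res.run_thresholds))
        assert len(res.run_thresholds) == 2
        assert all(len(log) == 78 for log in res.logs)

    def test_reproducible_under_equal_seed(self, canonical_participant):
        r1 = run_step_calibration(simulated_responder(
            canonical_participant, np.random.default_rng(99)))
        r2 = run_step_calibration(simulated_responder(
            canonical_participant, np.random.default_rng(99)))
        assert r1 == r2

    def test_boundary_non_increasing_and_intensities_clamped(
            self, canonical_participant):
        res = run_step_calibration(simulated_responder(
            canonical_participant, np.random.default_rng(17)))
        for log, traj in zip(res.logs, res.boundary_trajectory):
            assert np.all(np.diff(traj) <= 1e-12)
            for t, b in zip(log, [200.0] + traj[:-1]):
                assert 0.0 <= t.intensity <= b + 1e-9
                assert t.intensity <= 200.0

    def test_estimate_lies_within_incorrect_intensity_range(
            self, canonical_participant):
        res = run_step_calibration(simulated_responder(
            canonical_participant, np.random.default_rng(23)))
        for th, log in zip(res.run_thresholds, res.logs):
            wrong = [t.intensity for t in log if not t.correct]
            assert min(wrong) - 1e-9 <= th <= max(wrong) + 1e-9

    def test_run_log_replay_matches_reported_threshold(
            self, canonical_participant):
        # Eq.-oracle on the full controller: recompute each run's estimate
        # straight from its trial log.
        res = run_step_calibration(simulated_responder(
            canonical_participant, np.random.default_rng(31)))
        for th, log in zip(res.run_thresholds, res.logs):
            expected = brute_force_threshold([t.correct for t in log],
                                             [t.intensity for t in log])
            assert th == pytest.approx(expected, rel=1e-12)

    def test_all_correct_run_falls_back_to_scale_minimum(self):
        res = run_step_calibration(lambda x: (True, True),
                                   StepConfig(trials_per_run=20))
        assert res.final_threshold == 0.0
        assert "no_incorrect_responses" in res.flags

    def test_paired_mode_updates_only_on_pair_completion(self):
        cfg = StepConfig.isi_experiment(trials_per_run=6, n_runs=1,
                                        use_subjective=False)
        script = iter([(True, False), (True, False),    # pair: down
                       (True, False), (False, False),   # mixed: hold
                       (False, False), (False, False)]) # pair: up
        xs = []

        def responder(x):
            xs.append(x)
            return next(script)

        run_step_calibration(responder, cfg)
        down_one = 200.0 - 4 * step_mod.FRAME_MS  # one 4-frame step
        assert xs[0] == xs[1] == 200.0
        assert xs[2] == xs[3] == pytest.approx(down_one)
        assert xs[4] == xs[5] == pytest.approx(down_one)  # mixed pair held


class TestChanceNeutrality:
    def test_boundary_updates_rare_for_pure_chance_responder(self):
        # responder at exactly chance everywhere; count update events per test
        rng = np.random.default_rng(2024)
        cfg = StepConfig(trials_per_run=78, n_runs=1)
        n_tests = n_updates = 0
        for _ in range(30):
            def responder(x):
                return bool(rng.random() < 0.5), bool(rng.random() < 0.2)

            res = run_step_calibration(responder, cfg)
            traj = np.array(res.boundary_trajectory[0])
            drops = np.sum(np.diff(np.concatenate([[200.0], traj])) < -1e-12)
            n_tests += len(traj)
            n_updates += int(drops)
        rate = n_updates / n_tests
        # nominal alpha is at most 0.05 per test; allow binomial slack
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)
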