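"""Adaptive-participant simulator: learner recursion, mapping fidelity, protocol."""

import numpy as np
import pytest

from trackadapt import (
    LearnerState,
    SimConfig,
    TrialRecording,
    inject_blinks,
    make_trajectory,
    mean_distance,
    run_experiment,
    simulate_eye_trial,
    simulate_hand_trial,
    simulate_playback_trial,
    xcorr_lag_2d,
)
from trackadapt.simulate import _MINJERK_ACC, _saccade_duration_s
from trackadapt.trajectory import PointSeries, SamplingSpec, rotate_xy

TINY_PROTOCOL = (("baseline", 0.0, 2), ("rotation", 90.0, 3), ("washout", 0.0, 1))


@pytest.fixture(scope="module")
def target(patterns, timing):
    return make_trajectory(patterns[1], timing)


class TestHandTrial:
    def test_unperturbed_controller_tracks_closely(self, target):
        cfg = SimConfig(motor_noise_sd=0.0)
        rec, _ = simulate_hand_trial(LearnerState(), target, cfg, 0.0,
                                     np.random.default_rng(0))
        assert mean_distance(rec.cursor_xy, rec.target_xy, rec.fs) < 0.5

    def test_learner_matches_geometric_closed_form(self, target):
        """With full retention and no noise, residual error is 90*(1-alpha)^n."""
        alpha = 0.13
        cfg = SimConfig(retention=1.0, motor_noise_sd=0.0, alpha_hand=alpha)
        state = LearnerState()
        for n in range(1, 8):
            _, state = simulate_hand_trial(state, target, cfg, 90.0,
                                           np.random.default_rng(0))
            residual = 90.0 - state.theta_hat_hand
            assert residual == pytest.approx(90.0 * (1 - alpha) ** n, abs=1e-9)

    def test_naive_rotation_error_at_least_three_times_baseline(self, target):
        cfg = SimConfig()
        rec0, _ = simulate_hand_trial(LearnerState(), target, cfg, 0.0,
                                      np.random.default_rng(1))
        rec90, _ = simulate_hand_trial(LearnerState(), target, cfg, 90.0,
                                       np.random.default_rng(2))
        d0 = mean_distance(rec0.cursor_xy, rec0.target_xy, rec0.fs, rec0.valid)
        d90 = mean_distance(rec90.cursor_xy, rec90.target_xy, rec90.fs, rec90.valid)
        assert d90 >= 3 * d0

    def test_cursor_is_exact_rotation_of_hand(self, target):
        cfg = SimConfig()
        rec, _ = simulate_hand_trial(LearnerState(), target, cfg, 90.0,
                                     np.random.default_rng(3))
        assert np.allclose(rec.cursor_xy, rotate_xy(rec.hand_xy, 90.0),
                           atol=1e-12)


class TestEyeTrial:
    def test_perfect_prediction_short_lag_and_baseline_distance(self):
        cfg = SimConfig(motor_noise_sd=0.0, eye_noise_sd=0.0)
        state = LearnerState(theta_hat_eye=90.0)
        rec, _ = simulate_eye_trial(state, cfg, 90.0, np.random.default_rng(4))
        lag, _ = xcorr_lag_2d(rec.eye_xy, rec.target_xy, rec.fs, valid=rec.valid)
        assert lag < cfg.pursuit_lag_ms / 2
        assert mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid) < 1.0

    def test_naive_rotation_alters_tracking_then_adapts_within_ten_trials(self):
        cfg = SimConfig()
        rng = np.random.default_rng(5)
        state = LearnerState()
        base = []
        for _ in range(10):
            rec, state = simulate_eye_trial(state, cfg, 0.0, rng)
            base.append(mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid))
        errors = []
        for _ in range(10):
            rec, state = simulate_eye_trial(state, cfg, 90.0, rng)
            errors.append(mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid))
        b_mean, b_sd = np.mean(base), np.std(base)
        assert min(errors[:2]) > b_mean + 3 * b_sd
        assert errors[-1] <= b_mean + max(1 * b_sd, 0.1)

    def test_hand_adapted_state_transfers_fully_to_eye(self):
        """Prior hand adaptation leaves initial eye tracking unaltered."""
        cfg = SimConfig()
        rng = np.random.default_rng(6)
        base = []
        state = LearnerState()
        for _ in range(5):
            rec, state = simulate_eye_trial(state, cfg, 0.0, rng)
            base.append(mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid))
        adapted = LearnerState(theta_hat_hand=88.0)
        early = []
        for _ in range(2):
            rec, adapted = simulate_eye_trial(adapted, cfg, 90.0, rng)
            early.append(mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid))
        assert np.mean(early) < np.mean(base) + 3 * np.std(base) + 0.2


class TestPlaybackTrial:
    def test_playback_target_reproduces_self_moved_target(self):
        cfg = SimConfig()
        rec, _ = simulate_eye_trial(LearnerState(), cfg, 0.0,
                                    np.random.default_rng(7))
        tgt = PointSeries(rec.t_ms / 1000.0, rec.target_xy[:, 0],
                          rec.target_xy[:, 1])
        pb = simulate_playback_trial(tgt, cfg, np.random.default_rng(8))
        assert np.array_equal(pb.target_xy, rec.target_xy)

    def test_playback_doubles_lag_and_degrades_distance(self):
        """Reactive tracking of an external target: lag ~2x, larger distance."""
        cfg = SimConfig()
        lags_self, lags_pb, d_self, d_pb = [], [], [], []
        for seed in range(8):
            rec, _ = simulate_eye_trial(LearnerState(), cfg, 0.0,
                                        np.random.default_rng(300 + seed))
            tgt = PointSeries(rec.t_ms / 1000.0, rec.target_xy[:, 0],
                              rec.target_xy[:, 1])
            pb = simulate_playback_trial(tgt, cfg, np.random.default_rng(400 + seed))
            lags_self.append(xcorr_lag_2d(rec.eye_xy, rec.target_xy, rec.fs,
                                          valid=rec.valid)[0])
            lags_pb.append(xcorr_lag_2d(pb.eye_xy, pb.target_xy, pb.fs,
                                        valid=pb.valid)[0])
            d_self.append(mean_distance(rec.eye_xy, rec.target_xy, rec.fs, rec.valid))
            d_pb.append(mean_distance(pb.eye_xy, pb.target_xy, pb.fs, pb.valid))
        ratio = np.mean(lags_pb) / np.mean(lags_self)
        assert 1.5 < ratio < 2.8
        assert np.mean(d_pb) > np.mean(d_self)


class TestSaccadeKinematics:
    def test_generated_saccades_exceed_detection_threshold(self):
        """Minimum-jerk peak acceleration stays above 1500 deg/s^2 at any amplitude."""
        cfg = SimConfig()
        for amp in (0.2, 0.5, 1.0, 2.0, 5.0, 15.0, 30.0):
            dur = _saccade_duration_s(amp, cfg.saccade_peak_acc, 1000.0)
            peak = _MINJERK_ACC * amp / dur**2
            assert peak > 1500.0

    def test_config_rejects_undetectable_saccades(self):
        with pytest.raises(ValueError):
            SimConfig(saccade_peak_acc=1000.0)


class TestBlinks:
    def _recording(self, n=10_000):
        t = np.arange(n, dtype=float)
        xy = np.zeros((n, 2))
        return TrialRecording(t_ms=t, target_xy=xy, eye_xy=xy.copy(),
                              pupil=np.full(n, 1000.0),
                              valid=np.ones(n, dtype=bool))

    def test_zero_rate_leaves_all_samples_valid(self, rng):
        cfg = SimConfig(blink_rate_per_min=0.0)
        rec = inject_blinks(self._recording(), cfg, rng)
        assert rec.valid.all()

    def test_invalid_fraction_near_one_percent(self, rng):
        cfg = SimConfig()
        fracs = [1.0 - inject_blinks(self._recording(), cfg, rng).valid.mean()
                 for _ in range(100)]
        assert np.mean(fracs) == pytest.approx(0.009, abs=0.003)

    def test_blink_samples_have_zero_pupil(self, rng):
        cfg = SimConfig(blink_rate_per_min=30.0)
        rec = inject_blinks(self._recording(), cfg, rng)
        assert not rec.valid.all()
        assert np.all(rec.pupil[~rec.valid] == 0.0)


class TestRunExperiment:
    def test_trial_counts_per_participant(self):
        dataset = run_experiment(seed=0, participants_per_group=1)
        assert len(dataset) == 2 * 104
        one = [r for r in dataset if r.participant == "hand_first_p00"]
        assert len(one) == 104
        assert sum(r.task == "hand" for r in one) == 52

    def test_same_seed_reproduces_dataset_exactly(self, timing):
        kw = dict(seed=3, participants_per_group=1, protocol=TINY_PROTOCOL)
        d1 = run_experiment(**kw)
        d2 = run_experiment(**kw)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert np.array_equal(a.eye_xy, b.eye_xy)
            assert np.array_equal(a.target_xy, b.target_xy)
            assert np.array_equal(a.valid, b.valid)

    def test_patterns_balanced_within_hand_blocks(self):
        dataset = run_experiment(seed=4, participants_per_group=1)
        hand_rot = [r.pattern_id for r in dataset
                    if r.task == "hand" and r.phase == "rotation"
                    and r.participant == "hand_first_p00"]
        counts = np.bincount(hand_rot, minlength=6)[1:]
        assert (counts == 8).all()

    def test_washout_produces_aftereffects(self):
        """Post-washout error exceeds late-rotation error in both tasks."""
        dataset = run_experiment(seed=5, participants_per_group=1)
        from trackadapt.pipeline import metrics_table
        mt = metrics_table([r for r in dataset
                            if r.phase in ("rotation", "washout")
                            and (r.phase == "washout" or r.trial_index >= 39)])
        for task, col in (("hand", "cursor_target_cm"), ("eye", "eye_target_cm")):
            sub = mt[mt.task == task]
            late = sub[sub.phase == "rotation"][col].mean()
            post = sub[sub.phase == "washout"][col].mean()
            assert post > late
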