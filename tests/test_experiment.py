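import numpy as np
import pytest

from fogsim.basal_ganglia import PRESETS, CriticState
from fogsim.environment import Cause, TrackGeometry
from fogsim.experiment import (
    PROFILE_GRID,
    TrialRecord,
    _run_batch,
    compare_groups,
    doorway_statistics,
    interpolate_velocity,
    run_condition,
    run_episode,
    train_agent,
    value_landscape,
    velocity_profile,
)

NARROW = TrackGeometry.from_preset("narrow")


class TestInterpolation:
    def test_endpoints_and_midpoint(self):
        assert interpolate_velocity(1.0, 2.0, 0.0, 4.0, 0.0) == 1.0
        assert interpolate_velocity(1.0, 2.0, 0.0, 4.0, 2.0) == 1.5
        assert interpolate_velocity(1.0, 2.0, 0.0, 4.0, 1.0) == 1.25

    def test_zero_interval_rejected(self):
        with pytest.raises(ValueError):
            interpolate_velocity(1.0, 2.0, 3.0, 3.0, 3.0)

    def test_exact_on_affine_velocity_fields(self, rng):
        # linear interpolation reproduces any affine field exactly
        a, b = rng.normal(), rng.normal()
        X = np.sort(rng.uniform(0, 10, size=20))
        for xa, xb in zip(X[:-1], X[1:]):
            xr = 0.5 * (xa + xb)
            v = interpolate_velocity(a + b * xa, a + b * xb, xa, xb, xr)
            assert v == pytest.approx(a + b * xr, abs=1e-12)


class TestWelch:
    def test_identical_samples_give_p_one(self):
        x = np.full(10, 1.3)
        assert compare_groups(x, x.copy()).p == 1.0

    def test_type_one_error_calibration(self, rng):
        hits = 0
        n_rep = 1500
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 12))
            if compare_groups(a, b).p < 0.05:
                hits += 1
        assert 0.03 < hits / n_rep < 0.07

    def test_detects_shift(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)
        assert compare_groups(a, b).p < 1e-10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))


def _toy_trial(y, strides, x=None):
    n = len(y)
    x = np.zeros(n) if x is None else np.asarray(x, float)
    return TrialRecord(x, np.asarray(y, float), np.zeros(n),
                       np.ones(n), np.asarray(strides, float), Cause.PASSED_DOOR)


class TestDoorwayStatistics:
    def test_constant_strides_give_zero_cv(self):
        rec = _toy_trial(np.linspace(8.1, 9.9, 10), np.full(10, 0.5))
        s = doorway_statistics([[rec]], NARROW)
        assert s.cv_per_trial[0] == 0.0
        assert s.per_trial_mean[0] == pytest.approx(0.5)

    def test_population_sd_convention(self):
        # population SD of {0.4, 0.6} is 0.1 about the 0.5 mean
        rec = _toy_trial([8.5, 9.5], [0.4, 0.6])
        s = doorway_statistics([[rec]], NARROW)
        assert s.cv_per_trial[0] == pytest.approx(0.1 / 0.5)

    def test_window_mean_tracks_near_door_profile(self):
        # far-track strides only reach the window through interpolation up
        # to its first in-range grid point; a pass covering the window with
        # constant strides averages to that constant
        y = [1.0, 2.0] + list(np.arange(7.9, 10.0, 0.2))
        L = [9.0, 9.0] + [0.5] * len(np.arange(7.9, 10.0, 0.2))
        s = doorway_statistics([[_toy_trial(y, L)]], NARROW)
        assert s.per_trial_mean[0] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            doorway_statistics([], NARROW)


class TestEpisodes:
    def test_zero_training_passes_leave_weights_zero(self, stride_model, rng):
        critic = train_agent(PRESETS["cowie_control"], NARROW, stride_model, rng, n_passes=0)
        assert not np.any(critic.W)

    def test_same_seed_reproduces_training_bitwise(self, stride_model):
        a = train_agent(PRESETS["cowie_control"], NARROW, stride_model,
                        np.random.default_rng(7), n_passes=10)
        b = train_agent(PRESETS["cowie_control"], NARROW, stride_model,
                        np.random.default_rng(7), n_passes=10)
        assert np.array_equal(a.W, b.W)

    def test_episode_forward_progress_is_ratcheted(self, stride_model, rng):
        critic = CriticState.zeros(gamma=0.8)
        rec = run_episode(critic, PRESETS["cowie_control"], NARROW, stride_model, rng)
        dy = np.diff(rec.y)
        # y only retreats by the truncated backward displacement scale
        assert np.all(dy > -1e-3)

    def test_episode_ends_with_a_terminal_cause_or_cap(self, stride_model, rng):
        critic = CriticState.zeros(gamma=0.8)
        for _ in range(5):
            rec = run_episode(critic, PRESETS["cowie_control"], NARROW,
                              stride_model, rng, max_steps=300)
            assert rec.cause in (Cause.PASSED_DOOR, Cause.HIT_DOOR_POST, Cause.MAX_STEPS)

    def test_learning_changes_weights(self, stride_model, rng):
        critic = CriticState.zeros(gamma=0.8, eta=3e-4)
        run_episode(critic, PRESETS["cowie_control"], NARROW, stride_model, rng, learn=True)
        assert np.any(critic.W != 0.0)

    def test_batch_runner_matches_sequential_dynamics_statistically(self, stride_model):
        # same trained critic, same preset: the lock-step batch and the
        # sequential runner must generate indistinguishable step populations
        critic = train_agent(PRESETS["cowie_control"], NARROW, stride_model,
                             np.random.default_rng(3), n_passes=30)
        batch = _run_batch(critic, PRESETS["cowie_control"], NARROW, stride_model,
                           np.random.default_rng(11), n_passes=150)
        seq = [run_episode(critic, PRESETS["cowie_control"], NARROW, stride_model,
                           np.random.default_rng(1000 + i)) for i in range(150)]
        Lb = np.concatenate([r.stride for r in batch])
        Ls = np.concatenate([r.stride for r in seq])
        assert abs(np.mean(Lb) - np.mean(Ls)) < 0.05
        nb = np.mean([r.n_steps for r in batch])
        ns = np.mean([r.n_steps for r in seq])
        assert abs(nb - ns) / ns < 0.15


@pytest.fixture(scope="module")
def small_cell(stride_model):
    return run_condition("cowie_control", "narrow", stride_model,
                         np.random.SeedSequence(5), n_trials=4, passes_per_trial=25)


class TestConditionRuns:
    def test_summary_shapes(self, small_cell):
        assert small_cell.summary.n == 4
        assert small_cell.profiles.shape == (4, len(PROFILE_GRID))

    def test_determinism_per_seed(self, stride_model, small_cell):
        again = run_condition("cowie_control", "narrow", stride_model,
                              np.random.SeedSequence(5), n_trials=4, passes_per_trial=25)
        assert np.array_equal(again.summary.per_trial_mean, small_cell.summary.per_trial_mean)
        assert np.array_equal(again.critic.W, small_cell.critic.W)

    def test_normalized_profile_far_field_is_100(self, small_cell):
        prof = small_cell.group_profile
        far = (PROFILE_GRID >= 4.0) & (PROFILE_GRID <= 5.0)
        assert np.nanmean(prof[far]) == pytest.approx(100.0, abs=1.0)

    def test_trained_control_value_rises_toward_door_on_midline(self, stride_model):
        res = run_condition("cowie_control", "wide", stride_model,
                            np.random.SeedSequence(8), n_trials=2, passes_per_trial=10)
        xs, ys, V = value_landscape(res.critic, res.geometry)
        mid = V[:, len(xs) // 2]
        far = np.interp(6.0, ys, mid)
        near = np.interp(9.5, ys, mid)
        assert near > far

    def test_landscape_modes(self, small_cell):
        xs, ys, V = value_landscape(small_cell.critic, small_cell.geometry,
                                    mode="orientation_averaged", n_orientations=8)
        assert V.shape == (len(ys), len(xs))
        with pytest.raises(ValueError):
            value_landscape(small_cell.critic, small_cell.geometry, mode="sideways")


class TestVelocityProfile:
    def test_single_pass_interpolation(self):
        rec = TrialRecord(np.zeros(3), np.array([0.0, 5.0, 10.0]), np.zeros(3),
                          np.array([1.0, 2.0, 1.0]), np.ones(3), Cause.PASSED_DOOR)
        prof = velocity_profile([rec], normalize=False)
        assert prof[0] == pytest.approx(1.0)
        assert np.interp(2.5, PROFILE_GRID, prof) == pytest.approx(1.5)
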