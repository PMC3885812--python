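"""Protocols and statistics: training passes, test trials, velocity profiles,
stride/step statistics and group comparisons for the two doorway studies.

A *pass* is one walk from the start line toward the doorway; a *trial* is a
block of 100 passes from which one velocity profile and one per-trial mean
stride/step length are computed; a condition cell runs 50 such trials with
frozen critic weights after 100 training passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .basal_ganglia import (
    PRESETS,
    ConditionPreset,
    CriticState,
    DopamineMode,
    clamp_dopamine,
    gen_step,
)
from .environment import (
    Cause,
    RewardSchedule,
    StepOutcome,
    TrackGeometry,
    evaluate_step,
    reset_start,
)
from .locomotion import BACKWARD_STEP, GainParams, StrideModel
from .vision import N_SECTORS, view_vectors_batch

__all__ = [
    "TrialRecord",
    "GroupSummary",
    "WelchResult",
    "train_agent",
    "run_episode",
    "run_test_trials",
    "interpolate_velocity",
    "velocity_profile",
    "doorway_statistics",
    "compare_groups",
    "run_condition",
    "reproduce_cowie",
    "reproduce_almeida",
    "delta_lim_sweep",
    "gamma_sigma_effect",
    "value_landscape",
]

PROFILE_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)
FAR_FIELD = (4.0, 5.0)          # y-window (5-6 m before the door) for normalization
STATS_WINDOW_BEFORE_DOOR = 2.0  # y-extent of the stride/step averaging window
INITIAL_STEP = 0.1              # |dX(0)| seeding the GEN recursion (m, toward the door)


@dataclass
class TrialRecord:
    """Per-pass trajectory sampled at step-start positions."""

    x: np.ndarray
    y: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    stride: np.ndarray        # executed displacement magnitude per step (m)
    cause: Cause

    @property
    def passed(self) -> bool:
        return self.cause is Cause.PASSED_DOOR

    @property
    def n_steps(self) -> int:
        return len(self.stride)


def _switch_signal(gen_signal: str, dV, delta_clamped, mode: DopamineMode):
    if gen_signal == "delta_v" or mode is DopamineMode.CONTROL:
        return dV
    if gen_signal == "clamped_delta":
        return delta_clamped
    raise ValueError(f"unknown gen_signal {gen_signal!r}")


# ----------------------------------------------------------------------------
# Episode runners
# ----------------------------------------------------------------------------

def run_episode(
    critic: CriticState,
    preset: ConditionPreset,
    geometry: TrackGeometry,
    stride_model: StrideModel,
    rng: np.random.Generator,
    learn: bool = False,
    max_steps: int = 500,
    gen_signal: str = "delta_v",
    schedule: RewardSchedule = RewardSchedule(),
    gain: GainParams = GainParams(),
    wall_mode: str = "bounce",
    gaze_mode: str = "door_facing",
) -> TrialRecord:
    """One pass toward the doorway (sequential reference implementation).

    With ``learn=True`` the critic weights are updated in place by the
    clamped TD error at every transition.  ``wall_mode="bounce"`` (default)
    makes side-wall contact a punished, non-terminal event — the agent
    reflects off the wall line and walks on; ``"terminate"`` ends the pass
    there instead.
    """
    if wall_mode not in ("bounce", "terminate"):
        raise ValueError("wall_mode must be 'bounce' or 'terminate'")
    if gaze_mode not in ("door_facing", "displacement"):
        raise ValueError("gaze_mode must be 'door_facing' or 'displacement'")
    gen = preset.gen_params
    half_wall = geometry.x_max - geometry.agent_radius
    door_center = np.array([0.0, geometry.y_door])
    pos = reset_start(geometry, rng)
    ori = door_center - pos
    ori = ori / np.hypot(*ori)
    dX = INITIAL_STEP * ori
    phi = view_vectors_batch(pos[None, :], ori[None, :], geometry)[0]
    V = float(np.tanh(phi @ critic.W))

    rec_x, rec_y, rec_vx, rec_vy, rec_L = [], [], [], [], []
    cause = Cause.MAX_STEPS
    for _ in range(max_steps):
        v_x, v_y = float(dX[0]), float(dX[1])
        speed = float(np.hypot(v_x, v_y))
        if speed == 0.0:
            new_pos, L_exec = pos.copy(), 0.0
        else:
            L_exec = BACKWARD_STEP if v_y < 0 else float(stride_model.stride(v_x, v_y, gain))
            new_pos = pos + (L_exec / speed) * dX
        outcome = evaluate_step(geometry, schedule, pos, new_pos)
        if outcome.cause is Cause.HIT_WALL and wall_mode == "bounce":
            # elastic reflection off the wall line (still punished)
            new_pos[0] = np.clip(
                np.sign(new_pos[0]) * 2.0 * half_wall - new_pos[0],
                -half_wall, half_wall)
            outcome = StepOutcome(schedule.r_collision, Cause.ONGOING)

        rec_x.append(pos[0]); rec_y.append(pos[1])
        rec_vx.append(v_x); rec_vy.append(v_y); rec_L.append(L_exec)

        if outcome.terminal:
            V_new = 0.0
        else:
            if gaze_mode == "door_facing":
                d = door_center - new_pos
                ori = d / np.hypot(*d)
            elif speed > 0.0:
                ori = dX / speed
            phi_new = view_vectors_batch(new_pos[None, :], ori[None, :], geometry)[0]
            V_new = float(np.tanh(phi_new @ critic.W))

        delta = outcome.reward + critic.gamma * V_new - V
        delta_c = float(clamp_dopamine(delta, preset.dopamine))
        if learn:
            critic.W += critic.eta * delta_c * phi
        dV = V_new - V
        s = _switch_signal(gen_signal, dV, delta_c, preset.dopamine.mode)
        dX = gen_step(s, dX, gen, rng)

        if outcome.terminal:
            cause = outcome.cause
            break
        pos, V = new_pos, V_new
        phi = phi_new

    return TrialRecord(
        np.array(rec_x), np.array(rec_y), np.array(rec_vx),
        np.array(rec_vy), np.array(rec_L), cause,
    )


def train_agent(
    preset: ConditionPreset,
    geometry: TrackGeometry,
    stride_model: StrideModel,
    rng: np.random.Generator,
    n_passes: int = 100,
    eta: float = 3e-4,
    max_steps: int = 500,
    gen_signal: str = "delta_v",
    wall_mode: str = "bounce",
    gaze_mode: str = "door_facing",
) -> CriticState:
    """Build the value function over ``n_passes`` walks to the doorway."""
    critic = CriticState.zeros(N_SECTORS, eta=eta, gamma=preset.gamma)
    for _ in range(n_passes):
        run_episode(critic, preset, geometry, stride_model, rng,
                    learn=True, max_steps=max_steps, gen_signal=gen_signal,
                    wall_mode=wall_mode, gaze_mode=gaze_mode)
    return critic


def _run_batch(
    critic: CriticState,
    preset: ConditionPreset,
    geometry: TrackGeometry,
    stride_model: StrideModel,
    rng: np.random.Generator,
    n_passes: int,
    max_steps: int = 500,
    gen_signal: str = "delta_v",
    schedule: RewardSchedule = RewardSchedule(),
    gain: GainParams = GainParams(),
    wall_mode: str = "bounce",
    gaze_mode: str = "door_facing",
) -> list[TrialRecord]:
    """Frozen-weight passes advanced lock-step as one batch.

    Implements exactly the dynamics of :func:`run_episode` (weights frozen),
    vectorized over passes; terminated passes are masked out.
    """
    B = n_passes
    gen = preset.gen_params
    W = critic.W
    half_wall = geometry.x_max - geometry.agent_radius
    half_door = geometry.d_pos - geometry.agent_radius

    x0 = rng.uniform(-half_wall, half_wall, size=B)
    pos = np.stack([x0, np.full(B, geometry.y_start + 0.1)], axis=1)
    ori = np.stack([-x0, np.full(B, geometry.y_door - 0.1 - geometry.y_start)], axis=1)
    ori /= np.hypot(ori[:, 0], ori[:, 1])[:, None]
    dX = INITIAL_STEP * ori
    phi = view_vectors_batch(pos, ori, geometry)
    V = np.tanh(phi @ W)

    active = np.ones(B, dtype=bool)
    causes = np.full(B, Cause.MAX_STEPS, dtype=object)
    hist = {k: [] for k in ("x", "y", "vx", "vy", "L", "alive")}

    for _ in range(max_steps):
        v = dX
        speed = np.hypot(v[:, 0], v[:, 1])
        moving = active & (speed > 0.0)
        L = np.where(
            v[:, 1] < 0.0, BACKWARD_STEP,
            stride_model.stride(v[:, 0], v[:, 1], gain),
        )
        L = np.where(moving, L, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            step_vec = np.where(moving[:, None], (L / np.where(speed > 0, speed, 1.0))[:, None] * v, 0.0)
        new_pos = pos + step_vec

        hist["x"].append(pos[:, 0].copy()); hist["y"].append(pos[:, 1].copy())
        hist["vx"].append(v[:, 0].copy()); hist["vy"].append(v[:, 1].copy())
        hist["L"].append(L.copy()); hist["alive"].append(active.copy())

        # outcome classification: door-line crossing first, then wall contact
        crossed = active & (pos[:, 1] < geometry.y_door) & (new_pos[:, 1] >= geometry.y_door)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_frac = (geometry.y_door - pos[:, 1]) / np.where(
                new_pos[:, 1] != pos[:, 1], new_pos[:, 1] - pos[:, 1], 1.0)
        x_cross = pos[:, 0] + t_frac * (new_pos[:, 0] - pos[:, 0])
        passed = crossed & (np.abs(x_cross) <= half_door)
        post = crossed & ~passed
        wall = active & ~crossed & (np.abs(new_pos[:, 0]) > half_wall)
        if wall_mode == "bounce":
            new_pos[:, 0] = np.where(
                wall,
                np.clip(np.sign(new_pos[:, 0]) * 2.0 * half_wall - new_pos[:, 0],
                        -half_wall, half_wall),
                new_pos[:, 0])
            terminal = passed | post
        else:
            terminal = passed | post | wall
            causes[wall] = Cause.HIT_WALL
        reward = np.where(passed, schedule.r_pass,
                          np.where(wall | post, schedule.r_collision, schedule.r_elsewhere))
        causes[passed] = Cause.PASSED_DOOR
        causes[post] = Cause.HIT_DOOR_POST

        if gaze_mode == "door_facing":
            d = np.array([0.0, geometry.y_door]) - new_pos
            n = np.hypot(d[:, 0], d[:, 1])
            ori = d / np.where(n > 0, n, 1.0)[:, None]
        else:
            ori = np.where(moving[:, None], v / np.where(speed > 0, speed, 1.0)[:, None], ori)
        phi_new = view_vectors_batch(new_pos, ori, geometry)
        V_new = np.where(terminal, 0.0, np.tanh(phi_new @ W))

        delta = reward + critic.gamma * V_new - V
        delta_c = clamp_dopamine(delta, preset.dopamine)
        dV = V_new - V
        s = _switch_signal(gen_signal, dV, delta_c, preset.dopamine.mode)
        dX = gen_step(np.asarray(s), dX, gen, rng)

        active = active & ~terminal
        pos, V = new_pos, V_new
        if not active.any():
            break

    alive = np.stack(hist["alive"])           # (n_iter, B)
    records: list[TrialRecord] = []
    cols = {k: np.stack(hist[k]) for k in ("x", "y", "vx", "vy", "L")}
    for b in range(B):
        m = alive[:, b]
        records.append(TrialRecord(
            cols["x"][m, b], cols["y"][m, b], cols["vx"][m, b],
            cols["vy"][m, b], cols["L"][m, b], causes[b],
        ))
    return records


# ----------------------------------------------------------------------------
# Profiles
# ----------------------------------------------------------------------------

def interpolate_velocity(v_a, v_b, X_a, X_b, X_res):
    """Exact linear interpolation between two sampled velocities."""
    if np.any(X_a == X_b):
        raise ValueError("interpolation interval has zero length")
    return v_a + (v_b - v_a) * (X_res - X_a) / (X_b - X_a)


def _grid_profile(y: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """``values`` linearly interpolated against y on the grid; NaN outside
    the visited range."""
    if len(y) == 0:
        return np.full_like(grid, np.nan)
    order = np.argsort(y, kind="stable")
    y, values = y[order], values[order]
    if len(y) == 1:
        out = np.full_like(grid, np.nan)
        out[np.argmin(np.abs(grid - y[0]))] = values[0]
        return out
    out = np.interp(grid, y, values)
    out[(grid < y[0]) | (grid > y[-1])] = np.nan
    return out


def _pass_profile(rec: TrialRecord, grid: np.ndarray) -> np.ndarray:
    """Forward velocity v_y interpolated on the y grid (one pass)."""
    return _grid_profile(rec.y, rec.v_y, grid)


def velocity_profile(records: list[TrialRecord], grid: np.ndarray = PROFILE_GRID,
                     normalize: bool = True) -> np.ndarray:
    """Average forward-velocity profile over the passes of one trial.

    Normalized profiles are expressed as % of the far-field velocity
    (mean over y in [4, 5] m, i.e. 5-6 m before the door).
    """
    stack = np.stack([_pass_profile(r, grid) for r in records])
    with np.errstate(invalid="ignore"):
        prof = _nanmean_cols(stack)
    if not normalize:
        return prof
    far = (grid >= FAR_FIELD[0]) & (grid <= FAR_FIELD[1])
    ref = np.nanmean(prof[far])
    return 100.0 * prof / ref


def _nanmean_cols(stack: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (silently) for all-NaN columns."""
    cnt = np.sum(~np.isnan(stack), axis=0)
    tot = np.nansum(stack, axis=0)
    return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


# ----------------------------------------------------------------------------
# Statistics
# ----------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Per-trial mean stride/step lengths and within-trial step-length CV."""

    per_trial_mean: np.ndarray
    cv_per_trial: np.ndarray
    n: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_trial_mean))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.per_trial_mean, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n)

    @property
    def cv_mean(self) -> float:
        return float(np.nanmean(self.cv_per_trial))


def doorway_statistics(trials: list[list[TrialRecord]], geometry: TrackGeometry) -> GroupSummary:
    """Stride/step statistics per trial.

    The per-trial mean length follows the velocity-profile protocol: each
    pass's executed stride/step length is linearly interpolated along the
    track, the trial's passes are averaged pointwise, and the profile is
    averaged over the 2 m pre-door window (y in [y_door - 2, y_door]).
    Samples outside the door-consistency x-window (|x| <= 2 d_pos, clipped
    to the track) are excluded before interpolation.  The within-trial CV
    (population SD / mean) is taken over the executed forward steps of the
    door-facing window — backward commands suppressed to the 0.0001 m
    placeholder displacement are freeze markers, not steps, and are left
    out of the variability measure.
    """
    if not trials or not any(trials):
        raise ValueError("need at least one trial with recorded passes")
    x_half = min(2.0 * geometry.d_pos, geometry.x_max)
    y_lo = geometry.y_door - STATS_WINDOW_BEFORE_DOOR
    grid = PROFILE_GRID
    win = (grid >= y_lo) & (grid <= geometry.y_door)
    means, cvs = [], []
    for recs in trials:
        profs = []
        for r in recs:
            keep = np.abs(r.x) <= x_half
            profs.append(_grid_profile(r.y[keep], r.stride[keep], grid))
        prof = _nanmean_cols(np.stack(profs)) if profs else np.full_like(grid, np.nan)
        w = prof[win]
        means.append(float(np.nanmean(w)) if np.any(~np.isnan(w)) else np.nan)
        L = np.concatenate([r.stride for r in recs]) if recs else np.array([])
        y = np.concatenate([r.y for r in recs]) if recs else np.array([])
        L = L[(L > BACKWARD_STEP) & (y >= y_lo)]
        if L.size and np.mean(L) != 0:
            cvs.append(float(np.std(L) / np.mean(L)))
        else:
            cvs.append(np.nan)
    return GroupSummary(np.array(means), np.array(cvs), len(trials))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def compare_groups(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch two-sample t-test on per-trial means (unequal variances)."""
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float)
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two per-trial means per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(np.inf, float(len(a) + len(b) - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


# ----------------------------------------------------------------------------
# Condition cells and study reproductions
# ----------------------------------------------------------------------------

@dataclass
class ConditionResult:
    preset: ConditionPreset
    door: str
    geometry: TrackGeometry
    critic: CriticState
    trials: list[list[TrialRecord]]
    profiles: np.ndarray            # (n_trials, len(grid)) normalized
    summary: GroupSummary

    @property
    def group_profile(self) -> np.ndarray:
        return _nanmean_cols(self.profiles)

    def dip_depth(self, y_lo: float = 8.0) -> float:
        """100 minus the minimum normalized velocity within y_lo..door (%)."""
        grid = PROFILE_GRID
        near = (grid >= y_lo) & (grid <= self.geometry.y_door)
        return 100.0 - float(np.nanmin(self.group_profile[near]))


def run_test_trials(
    critic: CriticState,
    preset: ConditionPreset,
    geometry: TrackGeometry,
    stride_model: StrideModel,
    rng: np.random.Generator,
    n_trials: int = 50,
    passes_per_trial: int = 100,
    max_steps: int = 500,
    gen_signal: str = "delta_v",
    wall_mode: str = "bounce",
    gaze_mode: str = "door_facing",
) -> tuple[list[list[TrialRecord]], np.ndarray]:
    """Frozen-weight test phase: ``n_trials`` blocks of ``passes_per_trial``
    passes; returns the grouped records and normalized velocity profiles."""
    records = _run_batch(
        critic, preset, geometry, stride_model, rng,
        n_passes=n_trials * passes_per_trial, max_steps=max_steps,
        gen_signal=gen_signal, wall_mode=wall_mode, gaze_mode=gaze_mode,
    )
    trials = [records[i * passes_per_trial:(i + 1) * passes_per_trial]
              for i in range(n_trials)]
    profiles = np.stack([velocity_profile(t) for t in trials])
    return trials, profiles


def run_condition(
    preset: ConditionPreset | str,
    door: str,
    stride_model: StrideModel,
    seed_seq: np.random.SeedSequence,
    n_train: int = 100,
    n_trials: int = 50,
    passes_per_trial: int = 100,
    max_steps: int = 500,
    gen_signal: str = "delta_v",
    eta: float = 3e-4,
    wall_mode: str = "bounce",
    gaze_mode: str = "door_facing",
) -> ConditionResult:
    """Train the critic and run the full frozen-weight test block for one
    (condition, door) cell."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    geometry = TrackGeometry.from_preset(door)
    train_ss, test_ss = seed_seq.spawn(2)
    critic = train_agent(
        preset, geometry, stride_model, np.random.default_rng(train_ss),
        n_passes=n_train, eta=eta, max_steps=max_steps, gen_signal=gen_signal,
        wall_mode=wall_mode, gaze_mode=gaze_mode,
    )
    W_frozen = critic.W.copy()
    trials, profiles = run_test_trials(
        critic, preset, geometry, stride_model, np.random.default_rng(test_ss),
        n_trials=n_trials, passes_per_trial=passes_per_trial,
        max_steps=max_steps, gen_signal=gen_signal, wall_mode=wall_mode,
        gaze_mode=gaze_mode,
    )
    assert np.array_equal(critic.W, W_frozen)  # weights frozen during testing
    summary = doorway_statistics(trials, geometry)
    return ConditionResult(preset, door, geometry, critic, trials, profiles, summary)


def _study_bundle(results: dict[tuple[str, str], ConditionResult]) -> dict:
    rows = []
    for (cond, door), res in results.items():
        rows.append({
            "condition": cond, "door": door,
            "mean_length": res.summary.mean, "sd": res.summary.sd,
            "se": res.summary.se, "cv": res.summary.cv_mean,
            "n_trials": res.summary.n, "dip_depth": res.dip_depth(),
        })
    return {"results": results, "table": pd.DataFrame(rows)}


def _pairwise(results, pairs) -> pd.DataFrame:
    rows = []
    for (cond_a, door_a), (cond_b, door_b), label in pairs:
        a = results[(cond_a, door_a)].summary.per_trial_mean
        b = results[(cond_b, door_b)].summary.per_trial_mean
        w = compare_groups(a, b)
        rows.append({"comparison": label, "t": w.t, "df": w.df, "p": w.p})
    return pd.DataFrame(rows)


def reproduce_cowie(
    stride_model: StrideModel,
    seed: int,
    n_trials: int = 50,
    passes_per_trial: int = 100,
    n_train: int = 100,
    **kwargs,
) -> dict:
    """Doorway-velocity study: controls vs PD freezers ON/OFF medication,
    stride lengths and normalized velocity profiles on three doors."""
    conditions = ["cowie_control", "cowie_pd_on", "cowie_pd_off"]
    doors = ["wide", "medium", "narrow"]
    ss = np.random.SeedSequence(seed)
    keys = [(c, d) for c in conditions for d in doors]
    cells = dict(zip(keys, ss.spawn(len(keys))))
    results = {
        (cond, door): run_condition(cond, door, stride_model, cells[(cond, door)],
                                    n_train=n_train, n_trials=n_trials,
                                    passes_per_trial=passes_per_trial, **kwargs)
        for cond, door in keys
    }
    bundle = _study_bundle(results)
    pairs = []
    for cond in ("cowie_pd_on", "cowie_pd_off"):
        for other in ("wide", "medium"):
            pairs.append(((cond, "narrow"), (cond, other),
                          f"{cond}: narrow vs {other}"))
    bundle["door_comparisons"] = _pairwise(results, pairs)
    return bundle


def reproduce_almeida(
    stride_model: StrideModel,
    seed: int,
    n_trials: int = 50,
    passes_per_trial: int = 100,
    n_train: int = 100,
    **kwargs,
) -> dict:
    """Step-length study: controls vs PD non-freezers vs freezers (all ON);
    per-door step-length means +/- SD, CV, and freezer-deficit tests."""
    conditions = ["almeida_control", "almeida_nonfreezer", "almeida_freezer"]
    doors = ["wide", "medium", "narrow"]
    ss = np.random.SeedSequence(seed)
    spawned = ss.spawn(len(conditions) * len(doors))
    results = {}
    k = 0
    for cond in conditions:
        for door in doors:
            results[(cond, door)] = run_condition(
                cond, door, stride_model, spawned[k], n_train=n_train,
                n_trials=n_trials, passes_per_trial=passes_per_trial, **kwargs)
            k += 1
    bundle = _study_bundle(results)
    pairs = []
    for door in doors:
        pairs.append((("almeida_freezer", door), ("almeida_nonfreezer", door),
                      f"{door}: freezer vs nonfreezer"))
        pairs.append((("almeida_freezer", door), ("almeida_control", door),
                      f"{door}: freezer vs control"))
    bundle["group_comparisons"] = _pairwise(results, pairs)
    return bundle


def delta_lim_sweep(
    stride_model: StrideModel,
    seed: int,
    delta_lims=(-1.0, -0.5, -0.1, 0.5, 1.0),
    gamma: float = 0.8,
    sigma: float = 0.3,
    door: str = "narrow",
    n_trials: int = 30,
    passes_per_trial: int = 100,
    **kwargs,
) -> dict:
    """Dopamine-clamp sweep at control gamma/sigma on the narrow door.

    The clamp ceiling delta_lim only shapes value learning here (the GEN
    switch runs on delta_V), so stride lengths are expected to be
    insensitive to it — the model's non-dopamine account of FOG.
    """
    from .basal_ganglia import DopamineCondition

    ss = np.random.SeedSequence(seed)
    spawned = ss.spawn(len(delta_lims))
    summaries = {}
    for dl, cell_ss in zip(delta_lims, spawned):
        preset = ConditionPreset(
            name=f"sweep_dlim_{dl}", study="cowie", gamma=gamma, sigma=sigma,
            dopamine=DopamineCondition(DopamineMode.PD_OFF, dl, 0.0),
        )
        res = run_condition(preset, door, stride_model, cell_ss,
                            n_trials=n_trials, passes_per_trial=passes_per_trial,
                            **kwargs)
        summaries[dl] = res.summary
    rows = []
    lims = list(delta_lims)
    for i in range(len(lims)):
        for j in range(i + 1, len(lims)):
            w = compare_groups(summaries[lims[i]].per_trial_mean,
                               summaries[lims[j]].per_trial_mean)
            rows.append({"a": lims[i], "b": lims[j], "t": w.t, "p": w.p})
    return {"summaries": summaries, "pairwise": pd.DataFrame(rows)}


def gamma_sigma_effect(
    stride_model: StrideModel,
    seed: int,
    door: str = "narrow",
    n_trials: int = 30,
    passes_per_trial: int = 100,
    **kwargs,
) -> dict:
    """Lowering sigma (to 0.01) or gamma (to 0.1) from control levels, with
    the dopamine signal unclamped, shortens strides significantly."""
    ss = np.random.SeedSequence(seed)
    cells = ss.spawn(3)
    variants = {
        "control": ConditionPreset("var_control", "cowie", 0.8, 0.3,
                                   PRESETS["cowie_control"].dopamine),
        "low_sigma": ConditionPreset("var_low_sigma", "cowie", 0.8, 0.01,
                                     PRESETS["cowie_control"].dopamine),
        "low_gamma": ConditionPreset("var_low_gamma", "cowie", 0.1, 0.3,
                                     PRESETS["cowie_control"].dopamine),
    }
    summaries = {
        name: run_condition(p, door, stride_model, cell_ss, n_trials=n_trials,
                            passes_per_trial=passes_per_trial, **kwargs).summary
        for (name, p), cell_ss in zip(variants.items(), cells)
    }
    out = {"summaries": summaries}
    for name in ("low_sigma", "low_gamma"):
        out[name] = compare_groups(summaries["control"].per_trial_mean,
                                   summaries[name].per_trial_mean)
    return out


def value_landscape(
    critic: CriticState,
    geometry: TrackGeometry,
    mode: str = "door_facing",
    nx: int = 41,
    ny: int = 100,
    n_orientations: int = 36,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Value V on an (x, y) grid, door-facing or orientation-averaged."""
    xs = np.linspace(geometry.x_min, geometry.x_max, nx)
    ys = np.linspace(geometry.y_start, geometry.y_door - 0.05, ny)
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    door = np.array([0.0, geometry.y_door])
    if mode == "door_facing":
        ori = door - pts
        ori /= np.hypot(ori[:, 0], ori[:, 1])[:, None]
        phi = view_vectors_batch(pts, ori, geometry)
        V = np.tanh(phi @ critic.W)
    elif mode == "orientation_averaged":
        acc = np.zeros(len(pts))
        for th in np.linspace(0, 2 * np.pi, n_orientations, endpoint=False):
            ori = np.tile([np.cos(th), np.sin(th)], (len(pts), 1))
            phi = view_vectors_batch(pts, ori, geometry)
            acc += np.tanh(phi @ critic.W)
        V = acc / n_orientations
    else:
        raise ValueError("mode must be 'door_facing' or 'orientation_averaged'")
    return xs, ys, V.reshape(ny, nx)
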