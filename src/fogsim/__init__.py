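"""fogsim: a two-level model of Parkinsonian gait at doorways.

An actor-critic basal-ganglia controller (GO/EXPLORE/NOGO policy over a
learned value landscape, with a dopamine-clamped TD error) commands the
velocity of a walking agent; pools of adaptive Hopf oscillators translate
the command into hip/knee rhythms, and a two-link kinematic leg converts
joint-angle extrema into stride and step lengths.  The package reproduces
the simulated doorway effects: velocity dips near narrow doors, shortened
strides/steps in PD conditions, and elevated step-length variability in
freezers.
"""

from .basal_ganglia import (
    PRESETS,
    ConditionPreset,
    CriticState,
    DopamineCondition,
    DopamineMode,
    GENParams,
    clamp_dopamine,
    gen_step,
    gen_step_discrete,
    td_error,
    update_weights,
    value,
    value_difference,
)
from .cpg import (
    CPGNetwork,
    TeachParams,
    TeachSignals,
    free_run,
    generate_teach_signals,
    instantaneous_phase,
    step_rate,
    train_cpg,
)
from .environment import (
    DOOR_WIDTHS,
    Cause,
    RewardSchedule,
    StepOutcome,
    TrackGeometry,
    evaluate_step,
    reset_start,
)
from .experiment import (
    GroupSummary,
    TrialRecord,
    compare_groups,
    delta_lim_sweep,
    doorway_statistics,
    gamma_sigma_effect,
    interpolate_velocity,
    reproduce_almeida,
    reproduce_cowie,
    run_condition,
    run_episode,
    run_test_trials,
    train_agent,
    value_landscape,
    velocity_profile,
)
from .locomotion import (
    GainParams,
    GaitGeometry,
    StrideModel,
    advance_position,
    joint_extrema,
    modulate_amplitudes,
    stride_length,
    velocity_gain,
)
from .vision import Orientation, RayFan, build_ray_fan, view_vector, view_vectors_batch

__version__ = "0.1.0"


def default_stride_model(mode: str = "stride", max_cycles: int = 400,
                         tolerance: float = 0.05) -> StrideModel:
    """Train the default CPG on the default teach signals and wrap it for
    stride evaluation.  Deterministic (no randomness in CPG training)."""
    net = CPGNetwork()
    train_cpg(net, generate_teach_signals(), max_cycles=max_cycles,
              tolerance=tolerance)
    return StrideModel(net, GaitGeometry(mode=mode))
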