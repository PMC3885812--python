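"""From velocity command to stride: gain, amplitude modulation, kinematics.

The actor's commanded velocity is squashed into a gain k = A_k tanh(c_k |v|)
that scales the CPG output weights (and hence the joint-angle amplitudes).
Stride length follows from the hip-angle extrema of one gait cycle through
the two-link leg (thigh l1, shank l2):

    L_STR = 2 (l1 + l2) sin(theta_ext2 / 2) + 2 (l1 + l2) sin(theta_ext3 / 2)

step mode keeps only the first term (a single step).  The agent is then
displaced by L_STR along the unit velocity vector; a commanded backward
move (v_y < 0) is truncated to a 0.0001 m displacement so the agent never
walks meaningfully away from the door.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cpg import CPGNetwork, free_run

__all__ = [
    "GainParams",
    "GaitGeometry",
    "velocity_gain",
    "modulate_amplitudes",
    "joint_extrema",
    "stride_length",
    "advance_position",
    "StrideModel",
    "BACKWARD_STEP",
]

#: Displacement substituted when the commanded v_y is negative (m).
BACKWARD_STEP = 1e-4


@dataclass(frozen=True)
class GainParams:
    """k(t) = A_k tanh(c_k |v|); amplitude 3, slope 1 in all conditions."""

    A_k: float = 3.0
    c_k: float = 1.0

    def __post_init__(self) -> None:
        if self.A_k <= 0 or self.c_k <= 0:
            raise ValueError("gain amplitude and slope must be positive")


@dataclass(frozen=True)
class GaitGeometry:
    """Two-link leg: thigh 0.5 m, shank 0.6 m; stride or step accounting."""

    l1: float = 0.5
    l2: float = 0.6
    mode: str = "stride"

    def __post_init__(self) -> None:
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("link lengths must be positive")
        if self.mode not in ("stride", "step"):
            raise ValueError("mode must be 'stride' or 'step'")


def velocity_gain(v_x, v_y, params: GainParams = GainParams()):
    """k = A_k tanh(c_k ||v||); saturates below A_k.  Broadcasts over arrays."""
    speed = np.hypot(v_x, v_y)
    return params.A_k * np.tanh(params.c_k * speed)


def modulate_amplitudes(alpha0: np.ndarray, k):
    """alpha_f = alpha0 * k: uniform scaling of the CPG output weights."""
    return np.asarray(alpha0, dtype=float) * k


def joint_extrema(theta_h: np.ndarray) -> tuple[float, float]:
    """Magnitudes of the 2nd and 3rd hip extrema of one gait cycle.

    The closed hip cycle carries three extrema (heel strikes); the first and
    third coincide at the cycle boundary, so one period holds two distinct
    turning points.  They are located periodically (independent of the phase
    at which the cycle was sampled) and returned as (smaller, larger)
    magnitude — (theta_ext2, theta_ext3) in the gait-cycle numbering, where
    the single-peak step length uses theta_ext2.  Errors unless the period
    has exactly two turning points.
    """
    cyc = np.asarray(theta_h, dtype=float)
    if np.allclose(cyc, cyc[0]):
        raise ValueError("flat trajectory has no extrema")
    if np.isclose(cyc[0], cyc[-1]):
        cyc = cyc[:-1]
    T = len(cyc)
    sig2 = np.concatenate([cyc, cyc])
    d = np.diff(sig2)
    turns = np.where(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1
    in_period = turns[(turns >= T // 2) & (turns < T // 2 + T)]
    if len(in_period) != 2:
        raise ValueError(
            f"expected 2 turning points per gait cycle, found {len(in_period)}"
        )
    mags = sorted(abs(float(sig2[i])) for i in in_period)
    return mags[0], mags[1]


def stride_length(
    theta_ext2: float,
    theta_ext3: float,
    geometry: GaitGeometry = GaitGeometry(),
) -> float:
    """Two-step (stride) or single-step length from hip extrema magnitudes."""
    if theta_ext2 < 0 or theta_ext3 < 0:
        raise ValueError("extrema magnitudes must be nonnegative")
    leg = 2.0 * (geometry.l1 + geometry.l2)
    L = leg * np.sin(theta_ext2 / 2.0)
    if geometry.mode == "stride":
        L = L + leg * np.sin(theta_ext3 / 2.0)
    return float(L)


def advance_position(position: np.ndarray, L_str: float, v_x: float, v_y: float) -> np.ndarray:
    """Displace by L_STR along the unit velocity; backward commands are
    truncated to BACKWARD_STEP.  A zero velocity holds position."""
    position = np.asarray(position, dtype=float)
    speed = np.hypot(v_x, v_y)
    if speed == 0.0:
        return position.copy()
    if v_y < 0.0:
        L_str = BACKWARD_STEP
    return position + (L_str / speed) * np.array([v_x, v_y])


class StrideModel:
    """Analytic stride evaluation for a trained CPG.

    One free-run cycle of the converged network is stored; because the
    output Q = sum alpha p is linear in alpha, scaling the weights by the
    gain k scales the whole hip trace — and its extrema — by exactly k.
    ``integrated_hip_cycle`` re-runs the oscillator ODEs with the scaled
    weights for verification; the two routes agree to machine precision.
    """

    def __init__(self, network: CPGNetwork, geometry: GaitGeometry = GaitGeometry()):
        if network.alpha0 is None:
            raise ValueError("network must be trained first")
        self.network = network
        self.geometry = geometry
        _, Q = free_run(network, n_cycles=1)
        self.hip_cycle = np.append(Q[0], Q[0, 0])  # closed cycle
        self.e2, self.e3 = joint_extrema(self.hip_cycle)

    def extrema_at_gain(self, k):
        return k * self.e2, k * self.e3

    def stride(self, v_x, v_y, gain: GainParams = GainParams()):
        """Stride (or step) length for a velocity command; broadcasts."""
        k = velocity_gain(v_x, v_y, gain)
        leg = 2.0 * (self.geometry.l1 + self.geometry.l2)
        L = leg * np.sin(k * self.e2 / 2.0)
        if self.geometry.mode == "stride":
            L = L + leg * np.sin(k * self.e3 / 2.0)
        return L

    def integrated_hip_cycle(self, k: float) -> np.ndarray:
        """Hip trace over one cycle re-integrated with alpha_f = k * alpha0."""
        snap = self.network.snapshot()
        alpha_f = modulate_amplitudes(self.network.alpha0, k)
        T = int(round(1.0 / self.network.dt))
        out = np.empty(T + 1)
        for i in range(T):
            out[i] = float(np.sum(
                alpha_f[self.network.pool_idx == 0] * self.network.p[self.network.pool_idx == 0]
            ))
            self.network.rk4_step(None)
        out[T] = out[0]
        self.network.restore(snap)
        return out
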