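"""Actor-critic basal ganglia: value learning, TD error/dopamine, GEN policy.

The Critic estimates value V = tanh(W . phi) of the 50-sector view vector and
learns by the temporal-difference error delta = r + gamma*V(t) - V(t-1), the
model's dopamine correlate.  Parkinsonian conditions clamp delta to delta_lim
(OFF medication) and add delta_med on medication (ON).

The Actor is the GO/EXPLORE/NOGO (GEN) policy: stochastic hill-climbing on
the value landscape over position space.  When the last displacement raised
the value, repeat it (GO); when it lowered it, reverse (NOGO); in between,
move randomly (EXPLORE).  The continuous form blends the three regimes with
sigmoids and a Gaussian of the value difference:

    dX(t) = A_G sig(l_G s) dX(t-1) + A_E chi exp(-s^2/sigma^2)
            - A_N sig(l_N s) dX(t-1)

with s the switching signal (value difference, or clamped dopamine under PD)
and chi uniform in [-0.5, 0.5] per component.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CriticState",
    "DopamineMode",
    "DopamineCondition",
    "GENParams",
    "ConditionPreset",
    "PRESETS",
    "value",
    "td_error",
    "value_difference",
    "clamp_dopamine",
    "update_weights",
    "sig",
    "gen_step",
    "gen_step_discrete",
]


@dataclass
class CriticState:
    """Linear-tanh value function V = tanh(W . phi) with TD(0) learning."""

    W: np.ndarray
    eta: float = 0.1
    gamma: float = 0.8

    @classmethod
    def zeros(cls, n: int = 50, eta: float = 0.1, gamma: float = 0.8) -> "CriticState":
        return cls(W=np.zeros(n), eta=eta, gamma=gamma)

    def copy(self) -> "CriticState":
        return CriticState(self.W.copy(), self.eta, self.gamma)


class DopamineMode(str, enum.Enum):
    CONTROL = "control"
    PD_OFF = "pd_off"
    PD_ON = "pd_on"


@dataclass(frozen=True)
class DopamineCondition:
    """Clamping of the TD error: none (control), ceiling delta_lim (PD OFF),
    ceiling plus medication offset delta_med (PD ON)."""

    mode: DopamineMode = DopamineMode.CONTROL
    delta_lim: float = 0.0
    delta_med: float = 0.0

    def __post_init__(self) -> None:
        if self.mode is DopamineMode.PD_OFF and self.delta_med != 0.0:
            raise ValueError("PD OFF means no medication: delta_med must be 0")


@dataclass(frozen=True)
class GENParams:
    """Gains and slopes of the GO/EXPLORE/NOGO policy.

    A_G, A_N, A_E weight the three regimes; l_G > 0 and l_N < 0 are the
    sigmoid slopes; sigma is the width of the EXPLORE Gaussian (the
    exploration parameter).  D_hi / D_lo are only used by the discrete rule.
    """

    A_G: float = 2.5
    A_N: float = 1.0
    A_E: float = 1.0
    lambda_G: float = 1.0
    lambda_N: float = -1.0
    sigma: float = 0.3
    D_hi: float = 0.05
    D_lo: float = -0.05

    def __post_init__(self) -> None:
        if min(self.A_G, self.A_N, self.A_E) < 0:
            raise ValueError("regime gains must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (self.D_lo < 0 < self.D_hi):
            raise ValueError("need D_lo < 0 < D_hi")


def value(critic: CriticState, phi: np.ndarray) -> float:
    """V = tanh(W . phi); bounded in (-1, 1)."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != critic.W.shape[0]:
        raise ValueError("phi and W lengths differ")
    return np.tanh(phi @ critic.W)


def td_error(r: float, V_t: float, V_tm1: float, gamma: float):
    """delta = r + gamma*V(t) - V(t-1).  Pass V_t = 0 at terminal states."""
    return r + gamma * V_t - V_tm1


def value_difference(V_t: float, V_tm1: float):
    """delta_V = V(t) - V(t-1); equals delta when gamma = 1 and r = 0."""
    return V_t - V_tm1


def clamp_dopamine(delta, condition: DopamineCondition):
    """Apply the PD dopamine ceiling.

    control: identity.  pd_off: min(delta, delta_lim).
    pd_on: min(delta, delta_lim) + delta_med (the offset is added on both
    branches, shifting the whole clamped range up by the medication factor).
    Works elementwise on arrays.
    """
    if condition.mode is DopamineMode.CONTROL:
        return delta
    clamped = np.minimum(delta, condition.delta_lim)
    if condition.mode is DopamineMode.PD_ON:
        clamped = clamped + condition.delta_med
    return clamped


def update_weights(critic: CriticState, delta_clamped: float, phi: np.ndarray) -> CriticState:
    """In-place TD(0) update W += eta * delta * phi; returns the critic."""
    critic.W += critic.eta * delta_clamped * np.asarray(phi, dtype=float)
    return critic


def sig(x):
    """Logistic sigmoid 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def gen_step(
    switch: float,
    dX_prev: np.ndarray,
    params: GENParams,
    rng: np.random.Generator,
    chi: np.ndarray | None = None,
) -> np.ndarray:
    """Continuous GEN displacement update.

    ``switch`` is the dopamine switching signal (delta_V for controls, the
    clamped delta under PD).  ``chi`` may be injected for tests; otherwise a
    fresh uniform [-0.5, 0.5] draw per component.  Batched inputs broadcast:
    switch (B,), dX_prev (B, 2) -> (B, 2).
    """
    s = np.asarray(switch, dtype=float)
    dX_prev = np.asarray(dX_prev, dtype=float)
    if chi is None:
        chi = rng.uniform(-0.5, 0.5, size=dX_prev.shape)
    go = params.A_G * sig(params.lambda_G * s)
    nogo = params.A_N * sig(params.lambda_N * s)
    explore = params.A_E * np.exp(-(s**2) / params.sigma**2)
    if dX_prev.ndim == 2:
        go, nogo, explore = go[:, None], nogo[:, None], explore[:, None]
    return (go - nogo) * dX_prev + explore * chi


def gen_step_discrete(
    switch: float,
    dX_prev: np.ndarray,
    params: GENParams,
    rng: np.random.Generator,
    chi: np.ndarray | None = None,
) -> np.ndarray:
    """Three-branch GEN rule: GO repeats, NOGO reverses, EXPLORE is random.

    Reference form for the continuous policy; not used in the main runs.
    """
    dX_prev = np.asarray(dX_prev, dtype=float)
    if switch > params.D_hi:
        return dX_prev.copy()
    if switch <= params.D_lo:
        return -dX_prev
    if chi is None:
        chi = rng.uniform(-0.5, 0.5, size=dX_prev.shape)
    return np.asarray(chi, dtype=float)


@dataclass(frozen=True)
class ConditionPreset:
    """One column of the published condition tables: GEN gains plus the
    condition-specific (gamma, sigma, dopamine clamp) triple."""

    name: str
    study: str                      # "cowie" or "almeida"
    gamma: float
    sigma: float
    dopamine: DopamineCondition
    A_G: float = 2.5
    A_N: float = 1.0
    A_E: float = 1.0
    lambda_G: float = 1.0
    lambda_N: float = -1.0

    @property
    def gen_params(self) -> GENParams:
        return GENParams(
            A_G=self.A_G, A_N=self.A_N, A_E=self.A_E,
            lambda_G=self.lambda_G, lambda_N=self.lambda_N, sigma=self.sigma,
        )

    @property
    def step_mode(self) -> str:
        """Stride for the velocity/stride study, step for the step-length study."""
        return "step" if self.study == "almeida" else "stride"


def _preset(name, study, gamma, sigma, mode, delta_lim=0.0, delta_med=0.0):
    return ConditionPreset(
        name=name, study=study, gamma=gamma, sigma=sigma,
        dopamine=DopamineCondition(mode, delta_lim, delta_med),
    )


#: Published condition parameters.  The doorway-velocity study compares
#: controls with PD freezers OFF/ON medication; the step-length study
#: compares controls with PD non-freezers and freezers (all ON).
PRESETS: dict[str, ConditionPreset] = {
    "cowie_control": _preset("cowie_control", "cowie", 0.8, 0.3, DopamineMode.CONTROL),
    "cowie_pd_off": _preset("cowie_pd_off", "cowie", 0.1, 0.01, DopamineMode.PD_OFF, -0.1, 0.0),
    "cowie_pd_on": _preset("cowie_pd_on", "cowie", 0.1, 0.15, DopamineMode.PD_ON, -0.1, 0.12),
    "almeida_control": _preset("almeida_control", "almeida", 0.85, 0.23, DopamineMode.CONTROL),
    "almeida_nonfreezer": _preset(
        "almeida_nonfreezer", "almeida", 0.8, 0.22, DopamineMode.PD_ON, -0.1, 0.12
    ),
    "almeida_freezer": _preset(
        "almeida_freezer", "almeida", 0.75, 0.02, DopamineMode.PD_ON, -0.1, 0.12
    ),
}
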