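"""Central pattern generator: pools of adaptive Hopf oscillators.

Three pools (hip, knee1, knee2) of Hopf oscillators learn one gait cycle of
hip/knee joint-angle teach signals.  Each oscillator adapts its frequency
omega toward a Fourier component of the forcing error F = P_teach - Q_learned
and its output weight alpha toward that component's amplitude; once F has
decayed to zero the network free-runs the encoded rhythm.  Phase coupling
keeps oscillators locked within a pool (psi) and across pools (psi_G, with
the 0th hip oscillator as the global reference).

Per-oscillator dynamics (time derivatives, integrated with fixed-step RK4):

    dp  = xi (mu - z^2) p - omega q + eps F + tau sin(theta_IP - psi)
    dq  = xi (mu - z^2) q + omega p
    domega = -eps F q / z
    dalpha = eta_a p F
    dpsi   = sin((omega/omega_0) theta_IP_0 - theta_IP - psi)
    dpsi_G = sin(theta_IP_0,j-1 - theta_IP_0,j - psi_G)

with z = sqrt(p^2 + q^2) and theta_IP = sgn(p) arccos(-q/z).  mu sets the
limit-cycle amplitude (z -> sqrt(mu)), xi the relaxation speed, eps the
forcing/adaptation gain and tau the phase-coupling weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TeachParams",
    "TeachSignals",
    "generate_teach_signals",
    "count_extrema",
    "PoolSpec",
    "CPGNetwork",
    "instantaneous_phase",
    "hopf_derivatives",
    "train_cpg",
    "free_run",
    "step_rate",
    "HIP_POOL",
    "KNEE_POOL",
]

ETA_A = 0.08          # output-weight learning rate
_Z_FLOOR = 1e-9       # guard for the z divisions in the phase/frequency laws


# ----------------------------------------------------------------------------
# Teach signals
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class TeachParams:
    """Amplitudes (rad) and harmonic weights of the truncated-Fourier gait cycle.

    The hip swings at the 1 Hz stride frequency with a weak second harmonic,
    giving three extrema on the closed cycle (start, mid-cycle, end) — one
    per heel strike, i.e. 2 steps/s.  The knees flex once per step (2 Hz
    fundamental) and are exactly zero at the hip extrema.
    """

    hip_amp: float = 0.45
    hip_h2: float = 0.15
    knee_amp: float = 0.30
    knee_h2: float = 0.25
    knee_h3: float = 0.10


@dataclass(frozen=True)
class TeachSignals:
    """One gait cycle of joint-angle samples, t in [0, 1) s, T samples."""

    hip: np.ndarray
    knee1: np.ndarray
    knee2: np.ndarray
    T: int
    cycle_s: float = 1.0

    @property
    def dt(self) -> float:
        return self.cycle_s / self.T

    def pool(self, j: int) -> np.ndarray:
        return (self.hip, self.knee1, self.knee2)[j]

    def closed(self, j: int) -> np.ndarray:
        """Cycle with the wrap-around sample appended (closed interval)."""
        s = self.pool(j)
        return np.append(s, s[0])


def generate_teach_signals(T: int = 500, params: TeachParams | None = None) -> TeachSignals:
    """Deterministic truncated-Fourier hip/knee profiles for one gait cycle."""
    if T < 100:
        raise ValueError("need at least 100 samples per cycle")
    params = params or TeachParams()
    t = np.arange(T) / T
    hip = params.hip_amp * (np.cos(2 * np.pi * t) + params.hip_h2 * np.cos(4 * np.pi * t))
    knee = params.knee_amp * (
        np.sin(4 * np.pi * t)
        + params.knee_h2 * np.sin(8 * np.pi * t)
        + params.knee_h3 * np.sin(12 * np.pi * t)
    )
    # contralateral knee: same profile half a step (quarter cycle) later
    knee2 = params.knee_amp * (
        np.sin(4 * np.pi * (t + 0.25))
        + params.knee_h2 * np.sin(8 * np.pi * (t + 0.25))
        + params.knee_h3 * np.sin(12 * np.pi * (t + 0.25))
    )
    return TeachSignals(hip=hip, knee1=knee, knee2=knee2, T=T)


def count_extrema(signal: np.ndarray, include_ends: bool = True) -> int:
    """Count local extrema of a sampled trace.

    Interior slope sign changes always count.  With ``include_ends`` the two
    endpoints of a closed cycle count (once each) when the wrap point is a
    periodic extremum, i.e. the slope changes sign across the cycle boundary
    — this is how the three hip extrema of a gait cycle are tallied (the
    boundary heel-strike appears at both ends).
    """
    d = np.diff(signal)
    d = d[d != 0.0]
    if len(d) < 2:
        return 0
    n = int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
    if include_ends and np.sign(d[0]) != np.sign(d[-1]):
        n += 2
    return n


# ----------------------------------------------------------------------------
# Network structure and dynamics
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolSpec:
    """Per-pool Hopf constants and initial frequencies (rad/s)."""

    n_osc: int
    xi: float
    mu: float
    eps: float
    tau: float
    omega_init: tuple[float, ...]


TWO_PI = 2.0 * np.pi
#: Published pool constants: hip pool of 2 oscillators, knee pools of 3.
HIP_POOL = PoolSpec(2, xi=8.0, mu=1.0, eps=0.9, tau=2.0,
                    omega_init=(TWO_PI, 2 * TWO_PI))
KNEE_POOL = PoolSpec(3, xi=12.0, mu=1.0, eps=0.3, tau=1.0,
                     omega_init=(2 * TWO_PI, 4 * TWO_PI, 6 * TWO_PI))
DEFAULT_POOLS = (HIP_POOL, KNEE_POOL, KNEE_POOL)


def instantaneous_phase(p, q):
    """theta_IP = sgn(p) * arccos(-q / z), in [-pi, pi]; z = 0 is an error."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    z = np.hypot(p, q)
    if np.any(z == 0.0):
        raise ValueError("phase undefined at z = 0")
    s = np.where(p >= 0.0, 1.0, -1.0)
    return s * np.arccos(np.clip(-q / z, -1.0, 1.0))


class CPGNetwork:
    """Mutable state of the oscillator network plus its converged snapshot.

    Oscillators of all pools are stored in flat arrays; ``pool_idx`` maps the
    flat index to its pool and ``ref_idx`` to the pool's 0th (reference)
    oscillator.  ``prev_ref`` holds, for each pool, the flat index of the
    reference oscillator of the preceding pool (inter-pool phase chain), or
    -1 for the globally leading hip pool.
    """

    def __init__(self, pools: tuple[PoolSpec, ...] = DEFAULT_POOLS, dt: float = 1.0 / 500):
        self.pools = tuple(pools)
        self.dt = dt
        counts = [ps.n_osc for ps in pools]
        self.n_pools = len(pools)
        self.n_osc = int(np.sum(counts))
        self.pool_idx = np.repeat(np.arange(self.n_pools), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.ref_idx = starts[self.pool_idx]
        self.osc_in_pool = np.arange(self.n_osc) - starts[self.pool_idx]
        self.ref_of_pool = starts
        self.prev_ref = np.concatenate([[-1], starts[:-1]])
        self.xi = np.array([pools[j].xi for j in self.pool_idx])
        self.mu = np.array([pools[j].mu for j in self.pool_idx])
        self.eps = np.array([pools[j].eps for j in self.pool_idx])
        self.tau = np.array([pools[j].tau for j in self.pool_idx])
        self.eta_a = ETA_A
        self.reset_state()
        self.converged = False
        self.omega0: np.ndarray | None = None
        self.alpha0: np.ndarray | None = None

    def reset_state(self) -> None:
        self.p = np.full(self.n_osc, 1.0)
        self.q = np.zeros(self.n_osc)
        self.omega = np.concatenate([ps.omega_init for ps in self.pools]).astype(float)
        self.alpha = np.zeros(self.n_osc)
        self.psi = np.zeros(self.n_osc)
        self.psi_g = np.zeros(self.n_pools)

    # -- state vector packing -------------------------------------------------
    def _pack(self) -> np.ndarray:
        return np.concatenate([self.p, self.q, self.omega, self.alpha, self.psi, self.psi_g])

    def _unpack(self, y: np.ndarray) -> tuple[np.ndarray, ...]:
        m, k = self.n_osc, self.n_pools
        p, q, om, al, ps = (y[i * m:(i + 1) * m] for i in range(5))
        return p, q, om, al, ps, y[5 * m: 5 * m + k]

    def output_from(self, p: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        """Per-pool learned signal Q_j = sum_i alpha_ij p_ij."""
        return np.bincount(self.pool_idx, weights=alpha * p, minlength=self.n_pools)

    def output(self) -> np.ndarray:
        return self.output_from(self.p, self.alpha)

    # -- dynamics -------------------------------------------------------------
    def _rhs(self, y: np.ndarray, teach: np.ndarray | None) -> np.ndarray:
        p, q, om, al, ps, psg = self._unpack(y)
        z2 = p * p + q * q
        z = np.sqrt(z2)
        zs = np.maximum(z, _Z_FLOOR)
        theta = np.where(p >= 0.0, 1.0, -1.0) * np.arccos(np.clip(-q / zs, -1.0, 1.0))

        if teach is None:
            F_pool = np.zeros(self.n_pools)
        else:
            F_pool = teach - self.output_from(p, al)
        F = F_pool[self.pool_idx]

        theta_ref = theta[self.ref_idx]
        om_ref = om[self.ref_idx]
        is_ref = self.osc_in_pool == 0

        # phase mismatch of each oscillator against its recorded offset:
        # i >= 1 lock to the (frequency-ratio-scaled) pool reference via psi,
        # reference oscillators lock to the previous pool's reference via
        # psi_G; the hip reference leads and gets no coupling.  The same sine
        # drives both the phase memory (psi, psi_G) and the state coupling,
        # so the coupling vanishes once the offset is recorded and only acts
        # to undo drift.
        intra_err = np.sin(
            (om / np.maximum(om_ref, _Z_FLOOR)) * theta_ref - theta - ps
        )
        inter_err = np.zeros(self.n_pools)
        for j in range(self.n_pools):
            pr = self.prev_ref[j]
            if pr >= 0:
                r = self.ref_of_pool[j]
                inter_err[j] = np.sin(theta[pr] - theta[r] - psg[j])
        err = np.where(is_ref, inter_err[self.pool_idx], intra_err)
        has_coupling = ~is_ref | (self.prev_ref[self.pool_idx] >= 0)
        coupling = np.where(has_coupling, self.tau * err, 0.0)

        relax = self.xi * (self.mu - z2)
        dp = relax * p - om * q + self.eps * F + coupling
        dq = relax * q + om * p
        dom = -self.eps * F * q / zs
        dal = self.eta_a * p * F
        dps = np.where(is_ref, 0.0, intra_err)
        return np.concatenate([dp, dq, dom, dal, dps, inter_err])

    def rk4_step(self, teach: np.ndarray | None) -> np.ndarray:
        """Advance one dt (teach sample held constant over the step).
        Returns the pool forcing error F at the step start (zeros if free)."""
        y = self._pack()
        if teach is None:
            F0 = np.zeros(self.n_pools)
        else:
            F0 = teach - self.output()
        h = self.dt
        k1 = self._rhs(y, teach)
        k2 = self._rhs(y + 0.5 * h * k1, teach)
        k3 = self._rhs(y + 0.5 * h * k2, teach)
        k4 = self._rhs(y + h * k3, teach)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        self.p, self.q, self.omega, self.alpha, self.psi, self.psi_g = (
            a.copy() for a in self._unpack(y)[:6]
        )
        return F0

    # -- persistence ----------------------------------------------------------
    def snapshot(self) -> dict:
        return {
            "p": self.p.tolist(), "q": self.q.tolist(),
            "omega": self.omega.tolist(), "alpha": self.alpha.tolist(),
            "psi": self.psi.tolist(), "psi_g": self.psi_g.tolist(),
        }

    def restore(self, snap: dict) -> None:
        self.p = np.array(snap["p"])
        self.q = np.array(snap["q"])
        self.omega = np.array(snap["omega"])
        self.alpha = np.array(snap["alpha"])
        self.psi = np.array(snap["psi"])
        self.psi_g = np.array(snap["psi_g"])

    def save(self, path: str | Path) -> None:
        doc = {
            "dt": self.dt,
            "pools": [
                {"n_osc": ps.n_osc, "xi": ps.xi, "mu": ps.mu, "eps": ps.eps,
                 "tau": ps.tau, "omega_init": list(ps.omega_init)}
                for ps in self.pools
            ],
            "converged": self.converged,
            "omega0": None if self.omega0 is None else self.omega0.tolist(),
            "alpha0": None if self.alpha0 is None else self.alpha0.tolist(),
            "state": self.snapshot(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CPGNetwork":
        doc = json.loads(Path(path).read_text())
        pools = tuple(
            PoolSpec(d["n_osc"], d["xi"], d["mu"], d["eps"], d["tau"],
                     tuple(d["omega_init"]))
            for d in doc["pools"]
        )
        net = cls(pools=pools, dt=doc["dt"])
        net.restore(doc["state"])
        net.converged = doc["converged"]
        net.omega0 = None if doc["omega0"] is None else np.array(doc["omega0"])
        net.alpha0 = None if doc["alpha0"] is None else np.array(doc["alpha0"])
        return net


def hopf_derivatives(network: CPGNetwork, teach: np.ndarray | None = None) -> dict:
    """Right-hand sides at the network's current state (diagnostic view)."""
    d = network._rhs(network._pack(), teach)
    p, q, om, al, ps, psg = network._unpack(d)
    return {"dp": p, "dq": q, "domega": om, "dalpha": al, "dpsi": ps, "dpsi_g": psg}


# ----------------------------------------------------------------------------
# Training and free run
# ----------------------------------------------------------------------------

@dataclass
class TrainResult:
    converged: bool
    n_cycles: int
    rms_history: np.ndarray        # (n_cycles, n_pools) RMS forcing per cycle


def train_cpg(
    network: CPGNetwork,
    teach: TeachSignals,
    max_cycles: int = 400,
    tolerance: float = 0.05,
    raise_on_failure: bool = False,
) -> TrainResult:
    """Drive the network with the teach cycle until the forcing error dies.

    The 500-sample cycle is replayed until the per-pool RMS of F over a full
    cycle drops below ``tolerance`` (rad) for every pool, or ``max_cycles``
    is reached.  On success the converged (omega0, alpha0) are recorded and
    the forcing can be removed.
    """
    P = np.stack([teach.hip, teach.knee1, teach.knee2])  # (3, T)
    T = teach.T
    hist = []
    converged = False
    for cycle in range(max_cycles):
        sq = np.zeros(network.n_pools)
        for n in range(T):
            F = network.rk4_step(P[:, n])
            sq += F * F
        rms = np.sqrt(sq / T)
        hist.append(rms)
        if np.all(rms < tolerance):
            converged = True
            break
    if not converged and raise_on_failure:
        raise RuntimeError(f"CPG failed to converge in {max_cycles} cycles")
    network.converged = converged
    network.omega0 = network.omega.copy()
    network.alpha0 = network.alpha.copy()
    return TrainResult(converged, len(hist), np.array(hist))


def free_run(network: CPGNetwork, n_cycles: int = 1, mutate: bool = False):
    """Run the trained network with the forcing removed.

    Returns (t, Q) with Q of shape (n_pools, n_samples).  By default the
    network state is restored afterwards so a stored reference cycle can be
    replayed repeatably.
    """
    snap = network.snapshot()
    T = int(round(1.0 / network.dt))
    n = n_cycles * T
    Q = np.empty((network.n_pools, n))
    for k in range(n):
        Q[:, k] = network.output()
        network.rk4_step(None)
    t = np.arange(n) * network.dt
    if not mutate:
        network.restore(snap)
    return t, Q


def step_rate(hip_trace: np.ndarray, dt: float) -> float:
    """Steps per second measured as the inverse mean interval between
    successive hip-angle extrema (each extremum is one step)."""
    d = np.diff(hip_trace)
    idx = np.where(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1
    if len(idx) < 2:
        raise ValueError("too few extrema to measure a step rate")
    intervals = np.diff(idx) * dt
    return 1.0 / float(np.mean(intervals))
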