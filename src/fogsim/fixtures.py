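"""Deterministic fixtures for unit tests and by-hand checks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .basal_ganglia import PRESETS, CriticState
from .cpg import CPGNetwork, PoolSpec, TeachSignals, train_cpg
from .environment import TrackGeometry
from .experiment import run_episode
from .locomotion import GaitGeometry, StrideModel
from .vision import view_vectors_batch

__all__ = ["make_fixtures", "toy_cpg", "sinusoid_teach"]


def sinusoid_teach(freq_hz: float = 1.0, amp: float = 0.5, T: int = 500) -> TeachSignals:
    """Single-sinusoid teach cycle (same wave on all three pools).

    ``freq_hz`` should be an integer so the repeated 1 s cycle stays
    periodic; fractional frequencies introduce a wrap-around discontinuity.
    """
    t = np.arange(T) / T
    s = amp * np.cos(2 * np.pi * freq_hz * t)
    return TeachSignals(hip=s, knee1=s, knee2=s, T=T)


def toy_cpg(
    freq_hz: float = 1.0,
    amp: float = 0.5,
    max_cycles: int = 60,
    tolerance: float = 0.05,
    omega_init_hz: float | None = None,
) -> CPGNetwork:
    """A one-oscillator-per-pool network pre-converged on a pure sinusoid.

    ``omega_init_hz`` detunes the starting frequency to exercise the
    adaptive-frequency pull-in (defaults to the teach frequency).
    """
    w0 = 2 * np.pi * (omega_init_hz if omega_init_hz is not None else freq_hz)
    pool = PoolSpec(1, xi=8.0, mu=1.0, eps=0.9, tau=0.0, omega_init=(w0,))
    net = CPGNetwork(pools=(pool, pool, pool))
    train_cpg(net, sinusoid_teach(freq_hz, amp), max_cycles=max_cycles,
              tolerance=tolerance)
    return net


def scripted_poses() -> tuple[np.ndarray, np.ndarray]:
    """A short door-approach pose script (positions and unit orientations)."""
    ys = np.array([0.1, 2.0, 5.0, 8.0, 9.5])
    pos = np.stack([np.zeros_like(ys), ys], axis=1)
    ori = np.tile([0.0, 1.0], (len(ys), 1))
    return pos, ori


def make_fixtures(seed: int, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    geom = TrackGeometry.from_preset("narrow")
    pos, ori = scripted_poses()
    phi = view_vectors_batch(pos, ori, geom)
    p = out_dir / "view_vectors.json"
    p.write_text(json.dumps({
        "door": "narrow", "positions": pos.tolist(),
        "orientations": ori.tolist(), "phi": phi.astype(int).tolist(),
    }, indent=1))
    paths.append(p)

    net = toy_cpg()
    p = out_dir / "toy_cpg.json"
    net.save(p)
    paths.append(p)

    sm = StrideModel(net, GaitGeometry(mode="stride"))
    critic = CriticState.zeros()
    rng = np.random.default_rng(seed)
    episodes = []
    for _ in range(3):
        rec = run_episode(critic, PRESETS["cowie_control"], geom, sm, rng,
                          learn=True, max_steps=50)
        episodes.append({
            "x": rec.x.tolist(), "y": rec.y.tolist(),
            "stride": rec.stride.tolist(), "cause": rec.cause.value,
        })
    p = out_dir / "training_episode.json"
    p.write_text(json.dumps({"seed": seed, "episodes": episodes,
                             "final_W": critic.W.tolist()}, indent=1))
    paths.append(p)
    return paths
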