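"""Run configuration: a small, strictly-validated YAML schema.

Unknown keys are errors, not warnings; a config round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Parameters of one condition/door run.

    ``preset`` names a published condition column; any of gamma / sigma /
    delta_lim / delta_med may be overridden explicitly.  ``gen_signal``
    selects the GEN switching signal ("delta_v" per the model's account, or
    "clamped_delta").
    """

    preset: str = "cowie_control"
    door: str = "narrow"
    seed: int = 0
    n_train_passes: int = 100
    n_trials: int = 50
    passes_per_trial: int = 100
    max_steps: int = 500
    eta: float = 3e-4
    gen_signal: str = "delta_v"
    cpg_network: str | None = None      # path to a trained network file
    output_dir: str = "results"
    gamma: float | None = None
    sigma: float | None = None
    delta_lim: float | None = None
    delta_med: float | None = None

    def resolved_preset(self):
        from dataclasses import replace

        from .basal_ganglia import PRESETS, DopamineCondition

        p = PRESETS[self.preset]
        if self.gamma is not None:
            p = replace(p, gamma=self.gamma)
        if self.sigma is not None:
            p = replace(p, sigma=self.sigma)
        if self.delta_lim is not None or self.delta_med is not None:
            dop = DopamineCondition(
                p.dopamine.mode,
                p.dopamine.delta_lim if self.delta_lim is None else self.delta_lim,
                p.dopamine.delta_med if self.delta_med is None else self.delta_med,
            )
            p = replace(p, dopamine=dop)
        return p


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
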