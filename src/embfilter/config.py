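"""Merged run configuration: model + training + search + simulation sections.

YAML files map section names to field overrides; unknown sections or keys are
rejected so typos fail loudly.  Defaults equal the production values baked
into the per-section dataclasses.  One global seed fans out to per-stage
derived seeds so a full simulate -> train -> search -> benchmark run is
reproducible end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .model import ModelConfig
from .search import SearchConfig
from .synthetic import SimConfig
from .training import TrainingConfig

_SECTIONS = {
    "model": ModelConfig,
    "training": TrainingConfig,
    "search": SearchConfig,
    "sim": SimConfig,
}


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed (stable across runs)."""
        import zlib

        ss = np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stage.encode()),))
        return int(ss.generate_state(1)[0] % (2**31))

    def as_dict(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}
        out["seed"] = self.seed
        out["log_level"] = self.log_level
        return out


def _build_section(cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**overrides)


def load_run_config(path=None, text: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML; missing sections keep their defaults."""
    if text is None:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a YAML mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed", "log_level"}
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, dict(raw.get(name) or {}))
    return RunConfig(seed=int(raw.get("seed", 0)),
                     log_level=str(raw.get("log_level", "INFO")), **kwargs)
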