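"""Structured run configuration for the end-to-end pipeline.

One YAML (or JSON) file with per-stage sections mirroring the library's
config dataclasses.  Unknown keys are rejected so typos fail loudly, and
every pipeline run writes the fully resolved configuration next to its
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .nn.model import ModelConfig
from .sampling import GenerationConfig
from .training import FinetuneConfig, PretrainConfig

__all__ = ["DataConfig", "QSARConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class DataConfig:
    """Synthetic-data stage: corpus size and activity noise."""

    corpus_size: int = 5000
    corpus_seed: int = 7
    length_min: int = 8
    length_max: int = 36
    noise_sd: float = 0.3


@dataclass(frozen=True)
class QSARConfig:
    top: int = 100
    seed: int = 0


_SECTIONS = {
    "data": DataConfig,
    "model": ModelConfig,
    "pretrain": PretrainConfig,
    "finetune": FinetuneConfig,
    "generate": GenerationConfig,
    "qsar": QSARConfig,
}

#: Desk-scale defaults: a reduced model and a shape-preserving shrink of the
#: fine-tuning schedule, sized so the full pipeline runs in minutes on a CPU.
DESK_DEFAULTS = {
    "model": {"d_model": 64, "n_heads": 4, "n_blocks": 3, "adapter_dim": 16,
              "dropout": 0.1, "max_len": 72},
    "pretrain": {"epochs": 5, "batch_size": 256},
    "finetune": {"adapter_phase_len": 15, "main_phase_len": 10,
                 "max_epochs": 25, "cycle_len": 25, "n_cycles": 1,
                 "warmup_epochs": 5, "peak_lr": 3e-3, "batch_size": 64,
                 "patience": 5},
    "generate": {"n_samples": 1000, "temperature": 1.5},
}


@dataclass
class RunConfig:
    """Global seed, output directory and per-stage sections."""

    seed: int = 0
    outdir: Path = Path("runs/default")
    data: DataConfig = field(default_factory=DataConfig)
    model: dict = field(default_factory=dict)       # vocab_size filled at run time
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    generate: dict = field(default_factory=dict)
    qsar: QSARConfig = field(default_factory=QSARConfig)

    def resolved(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x):
                return dataclasses.asdict(x)
            if isinstance(x, Path):
                return str(x)
            return x
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def _build_section(name: str, payload: dict):
    cls = _SECTIONS[name]
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    return payload if name in ("model", "generate") else cls(**payload)


def load_config(path: str | Path | None = None,
                desk_scale: bool = True,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration.

    With ``desk_scale`` (the default) unspecified sections start from the
    reduced desk-scale defaults rather than the full-scale reference values.
    """
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
    if overrides:
        for key, sub in overrides.items():
            if isinstance(sub, dict):
                payload.setdefault(key, {}).update(sub)
            else:
                payload[key] = sub
    known = {"seed", "outdir"} | set(_SECTIONS)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig()
    cfg.seed = int(payload.get("seed", 0))
    cfg.outdir = Path(payload.get("outdir", "runs/default"))
    for name in _SECTIONS:
        section = dict(DESK_DEFAULTS.get(name, {})) if desk_scale else {}
        section.update(payload.get(name, {}))
        setattr(cfg, name, _build_section(name, section))
    return cfg


def write_resolved(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.resolved(), indent=1, default=str))
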