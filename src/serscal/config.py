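"""YAML run configuration for the end-to-end pipeline."""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .chemometrics import TrainConfig
from .preprocess import ALSParams
from .simulate import NoiseConfig
from .validation import BootstrapConfig

__all__ = ["SimulateConfig", "RunConfig", "load_config", "dump_config"]

_REQUIRED_BLOCKS = ("simulate", "preprocess", "model", "bootstrap")


@dataclass(frozen=True)
class SimulateConfig:
    """Design and noise settings of the synthetic campaign."""

    step: float = 0.1
    replicates: int = 3
    total_conc: float = 1e-5
    grid_start: float = 200.0
    grid_end: float = 3400.0
    grid_points: int = 1024
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass(frozen=True)
class ModelConfig:
    """Network topologies and training settings to evaluate."""

    topologies: tuple[str, ...] = ("1024-20-1", "1024-20-3")
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass(frozen=True)
class RunConfig:
    """Versioned, round-trippable pipeline configuration."""

    version: int = 1
    seed: int = 42
    output_dir: str = "serscal_out"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: ALSParams = field(default_factory=ALSParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    # shipped default: 200 desk-scale iterations (the full procedure uses 1000)
    bootstrap: BootstrapConfig = field(
        default_factory=lambda: BootstrapConfig(n_iterations=200)
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["topologies"] = list(self.model.topologies)
        return d

    def digest(self) -> str:
        """Stable hash of the canonicalised configuration."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"invalid config block {path!r}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Validate and build a RunConfig from a parsed YAML mapping."""
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    missing = [b for b in _REQUIRED_BLOCKS if b not in data]
    if missing:
        raise ValueError(f"config missing required block(s): {missing}")
    sim = dict(data["simulate"])
    noise = _build(NoiseConfig, sim.pop("noise", {}), "simulate.noise")
    simulate = _build(SimulateConfig, {**sim, "noise": noise}, "simulate")
    preprocess = _build(ALSParams, data["preprocess"], "preprocess")
    mdl = dict(data["model"])
    train = _build(TrainConfig, mdl.pop("train", {}), "model.train")
    topologies = tuple(mdl.pop("topologies", ("1024-20-1", "1024-20-3")))
    model = _build(
        ModelConfig, {"topologies": topologies, "train": train, **mdl}, "model"
    )
    bootstrap = _build(BootstrapConfig, data["bootstrap"], "bootstrap")
    top = {
        k: v
        for k, v in data.items()
        if k in ("version", "seed", "output_dir", "log_level")
    }
    return RunConfig(
        simulate=simulate,
        preprocess=preprocess,
        model=model,
        bootstrap=bootstrap,
        **top,
    )


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
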