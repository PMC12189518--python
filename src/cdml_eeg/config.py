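"""Pipeline configuration: one object that fixes every tunable of the chain
raw trials -> band-pass -> CWT -> image -> depth stack -> classifier -> CV.

Configs serialise to/from YAML (the CLI's ``--config``) and expose a stable
fingerprint used to key tensor caches and to stamp reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .preprocess import FilterSpec
from .synthetic import SyntheticSpec
from .tfr import MorletParams

__all__ = ["TrainConfig", "PipelineConfig"]

CHANNEL_ORDER = ("C3", "Cz", "C4")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for the classification head (Adam throughout)."""

    learning_rate: float = 0.001
    epochs: int = 150
    batch_size: int = 32
    val_fraction: float = 0.1  # inner validation split used for model selection
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end experiment description."""

    # data source: number of simulated subjects, or a directory of recordings
    n_subjects: int = 9
    data_dir: str | None = None
    window_seconds: float = 5.0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    # signal chain
    filter: FilterSpec = field(default_factory=FilterSpec)
    omega0: float = 6.0
    n_scales: int = 250
    band: tuple[float, float] = (8.0, 30.0)
    power: bool = False  # render |W|^2 instead of |W|
    out_size: tuple[int, int] = (250, 250)
    channel_order: tuple[str, str, str] = CHANNEL_ORDER

    # classifier
    backbone: str = "efficientnet-b0"
    pretrained: bool = False
    weights_path: str | None = None
    input_mode: str = "cdml"  # or a single channel: "C3" | "Cz" | "C4"
    train: TrainConfig = field(default_factory=TrainConfig)

    # evaluation
    k_folds: int = 10
    seed: int = 0

    @property
    def morlet(self) -> MorletParams:
        return MorletParams(omega0=self.omega0)

    # ------------------------------------------------------------- (de)serial
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            data["synthetic"] = SyntheticSpec(**_tupled(data["synthetic"]))
        if "filter" in data and isinstance(data["filter"], dict):
            data["filter"] = FilterSpec(**_tupled(data["filter"]))
        if "train" in data and isinstance(data["train"], dict):
            data["train"] = TrainConfig(**data["train"])
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**_tupled(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    def fingerprint(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_TUPLE_KEYS = {"band", "out_size", "channel_order", "mu_band", "beta_band",
               "mi_window", "rest_range"}


def _tupled(data: dict) -> dict:
    """YAML gives lists where the dataclasses want tuples."""
    return {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
            for k, v in data.items()}
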