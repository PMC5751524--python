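"""Hyperparameter and run configuration.

Names mirror the model's standard parameterization: ``dw`` word-embedding
dimension, ``dp`` distance-code width, ``num`` LSTM hidden units, ``rho``
dropout ratio (read as the KEEP probability; set ``rho_is_keep=False`` for
the drop-probability reading), ``l2`` regularization weight, ``la`` Adam
learning rate, and the sampling parameters ``alpha`` (negative
undersampling), ``beta`` and ``K`` (minority oversampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class HyperParams:
    # architecture (defaults are the model's published configuration)
    dw: int = 100
    dp: int = 10
    num: int = 300
    rho: float = 0.7
    rho_is_keep: bool = True
    full_peepholes: bool = False
    channels: tuple[str, ...] = ("linear", "dfs", "bfs")
    # optimization
    l2: float = 0.001
    la: float = 0.01
    batch_size: int = 64
    max_epochs: int = 30
    clip_norm: float = 5.0
    dev_fraction: float = 0.1
    patience: int = 5
    parameter_averaging: bool = True
    # sampling
    alpha: float = 0.5
    beta: float = 0.5
    K: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha <= 1 or not 0 < self.beta <= 1:
            raise ConfigError("alpha and beta must lie in (0, 1]")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if not 0 < self.rho <= 1:
            raise ConfigError("rho must lie in (0, 1]")
        for name in ("dw", "dp", "num", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        unknown = set(self.channels) - {"linear", "dfs", "bfs"}
        if unknown or not self.channels:
            raise ConfigError(f"bad channel list {self.channels}")
        self.channels = tuple(self.channels)

    @property
    def keep_prob(self) -> float:
        return self.rho if self.rho_is_keep else 1.0 - self.rho

    @property
    def input_dim(self) -> int:
        return self.dw + 2 * self.dp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HyperParams":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
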