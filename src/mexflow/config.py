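"""Run configuration: one YAML-serializable object per run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .types import NetConfig, TrainConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Merged network, training and preprocessing settings plus paths.

    Serialized next to every run so a stamp (config + seed) reproduces the
    metrics exactly on CPU. Round-trips losslessly through YAML.
    """

    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    preprocess: dict = field(default_factory=lambda: {
        "triplet_size": 28, "frame_size": [170, 140]})
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"] = dict(self.preprocess)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(net=NetConfig(**d.get("net", {})),
                   train=TrainConfig(**d.get("train", {})),
                   preprocess=dict(d.get("preprocess", {})),
                   paths=dict(d.get("paths", {})))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
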