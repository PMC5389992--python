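"""Pipeline configuration: one validated object covering every stage."""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .hierarchical import PriorSpec
from .synthetic import (
    DEFAULT_GROUP_MEANS_PROBIT,
    DEFAULT_GROUP_SDS_PROBIT,
    CouplingSpec,
)
from .task import TaskDesign


@dataclass(frozen=True)
class SamplerSettings:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        if self.n_chains < 2:
            raise ValueError("n_chains must be at least 2")
        if self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("warmup and sample counts must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 20
    group_means_probit: tuple[float, float, float] = DEFAULT_GROUP_MEANS_PROBIT
    group_sds_probit: tuple[float, float, float] = DEFAULT_GROUP_SDS_PROBIT
    design: TaskDesign = field(default_factory=TaskDesign)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if len(self.group_means_probit) != 3 or len(self.group_sds_probit) != 3:
            raise ValueError("group probit means/SDs must each have 3 entries")
        if any(s <= 0 for s in self.group_sds_probit):
            raise ValueError("group probit SDs must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "design" in kwargs:
            d = dict(kwargs["design"])
            if "pairs" in d:
                d["pairs"] = tuple(d["pairs"])
            kwargs["design"] = TaskDesign(**d)
        if "coupling" in kwargs:
            kwargs["coupling"] = CouplingSpec(**kwargs["coupling"])
        if "priors" in kwargs:
            kwargs["priors"] = PriorSpec(**kwargs["priors"])
        if "sampler" in kwargs:
            kwargs["sampler"] = SamplerSettings(**kwargs["sampler"])
        for key in ("group_means_probit", "group_sds_probit"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
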