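"""Structured pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bayes.mixedlm import LADDER
from .simulate.cohort import CohortDesign
from .simulate.ephys import CouplingDesign

__all__ = ["PipelineConfig", "load_config", "default_demo_config"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, in one reproducible object."""

    out_dir: str = "moveson-run"
    seed: int = 0
    cohort: CohortDesign = field(default_factory=CohortDesign)
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    sampler_steps: int = 1000
    clinical_n_per_group: int = 14
    clinical_scales: tuple[str, ...] = ("FM.A-D", "ARAT", "SIS.1")
    ephys: CouplingDesign = field(default_factory=CouplingDesign)
    ephys_post: CouplingDesign | None = None
    n_permutations: int = 500
    standardize_outcome: bool = True

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in LADDER]
        if bad:
            raise ValueError(f"unknown ladder models: {bad}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortDesign(**d["cohort"])
        for key in ("ephys", "ephys_post"):
            if isinstance(d.get(key), dict):
                kw = dict(d[key])
                if "coupled_channels" in kw:
                    kw["coupled_channels"] = tuple(kw["coupled_channels"])
                d[key] = CouplingDesign(**kw)
        for key in ("models", "clinical_scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def default_demo_config(out_dir: str = "moveson-demo",
                        seed: int = 0) -> PipelineConfig:
    """A small, fast demonstration run (minutes, not hours)."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        cohort=CohortDesign(n_treatment=6, n_control=6, n_sessions=4,
                            seed=seed),
        models=(1, 2, 3, 4, 5),
        sampler_steps=800,
        clinical_n_per_group=14,
        ephys=CouplingDesign(coupling_strength=0.2, n_trials=40,
                             coupled_channels=("C3", "F3", "P3"), seed=seed),
        ephys_post=CouplingDesign(coupling_strength=0.8, n_trials=40,
                                  coupled_channels=("C3", "F3", "P3"),
                                  seed=seed + 1),
        n_permutations=300,
    )
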