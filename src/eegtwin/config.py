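"""Serializable run configuration for the end-to-end pipeline.

A PipelineConfig captures everything needed to regenerate a result:
preprocessing references, the filter bank, CSP settings, the classifier and
kernel, optional hyperparameter optimization, fold counts and the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import yaml

from .classifiers import KernelSpec
from .optimizers import OptimizerConfig
from .preprocess import FilterBankSpec

_FAMILIES = ("lstwsvm", "twsvm", "svm")


@dataclass
class PipelineConfig:
    """Full pipeline settings; serializable and sufficient to reproduce a run."""

    reference_channels: Optional[List[str]] = None  # None = auto-detect "EOG*"
    filter_bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    csp_components: int = 4
    csp_regularization: float = 0.05
    classifier: str = "lstwsvm"
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec(family="rbf", gamma=0.5))
    costs: Tuple[float, float] = (1.0, 1.0)
    optimizer: Optional[OptimizerConfig] = None     # None = fixed costs, no tuning
    optimizer_folds: int = 10        # inner CV folds for the tuning fitness
    band_folds: int = 5              # inner CV folds for band selection
    outer_folds: int = 10            # outer CV folds for the reported accuracy
    pnn_bandwidth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in _FAMILIES:
            raise ValueError(f"classifier must be one of {_FAMILIES}")
        for name in ("outer_folds", "band_folds", "optimizer_folds"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "reference_channels": self.reference_channels,
            "filter_bank": {
                "bands": [list(b) for b in self.filter_bank.bands],
                "filter_order": self.filter_bank.filter_order,
                "design": self.filter_bank.design,
            },
            "csp_components": self.csp_components,
            "csp_regularization": self.csp_regularization,
            "classifier": self.classifier,
            "kernel": dataclasses.asdict(self.kernel),
            "costs": list(self.costs),
            "optimizer": (None if self.optimizer is None
                          else dataclasses.asdict(self.optimizer)),
            "optimizer_folds": self.optimizer_folds,
            "band_folds": self.band_folds,
            "outer_folds": self.outer_folds,
            "pnn_bandwidth": self.pnn_bandwidth,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fb = d.get("filter_bank")
        if isinstance(fb, dict):
            d["filter_bank"] = FilterBankSpec(
                bands=[tuple(b) for b in fb["bands"]],
                filter_order=fb.get("filter_order", 4),
                design=fb.get("design", "butter"),
            )
        k = d.get("kernel")
        if isinstance(k, dict):
            d["kernel"] = KernelSpec(**k)
        opt = d.get("optimizer")
        if isinstance(opt, dict):
            opt = dict(opt)
            if opt.get("acceleration") is not None:
                opt["acceleration"] = tuple(opt["acceleration"])
            if opt.get("inertia") is not None:
                opt["inertia"] = tuple(opt["inertia"])
            d["optimizer"] = OptimizerConfig(**opt)
        if d.get("costs") is not None:
            d["costs"] = tuple(d["costs"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
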