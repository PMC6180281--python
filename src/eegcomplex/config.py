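"""Flat analysis configuration, loadable from a YAML key-value file."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .montage import GROUPS
from .types import SampEnParams

DEFAULT_BINS: tuple[tuple[int, int], ...] = ((1, 4), (5, 8), (9, 12), (13, 16), (17, 20))

METHODS = ("lasso", "enet", "lr")


@dataclass
class ClassifyConfig:
    method: str = "lasso"
    alpha: float = 0.7  # used by enet; lasso forces 1.0, lr ignores
    lambda_grid_size: int = 50
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_grid_size < 2:
            raise ValueError("lambda_grid_size must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @property
    def effective_alpha(self) -> float:
        return 1.0 if self.method == "lasso" else self.alpha


@dataclass
class AnalysisConfig:
    mse: SampEnParams = field(default_factory=SampEnParams)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    contrast: tuple[str, str] = ("HC", "AD3")  # (negative, positive)
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        self.contrast = tuple(self.contrast)
        if len(self.contrast) != 2 or len(set(self.contrast)) != 2:
            raise ValueError("contrast must be two distinct group labels")
        for g in self.contrast:
            if g not in GROUPS:
                raise ValueError(f"contrast: unknown group {g!r}")
        self.bins = tuple((int(lo), int(hi)) for lo, hi in self.bins)
        covered = [s for lo, hi in self.bins for s in range(lo, hi + 1)]
        if sorted(covered) != list(range(1, self.mse.max_scale + 1)):
            raise ValueError(
                f"bins {self.bins} do not partition 1..{self.mse.max_scale}"
            )

    def to_flat_dict(self) -> dict:
        return {
            "mse_m": self.mse.m,
            "mse_r_frac": self.mse.r_frac,
            "mse_max_scale": self.mse.max_scale,
            "classify_method": self.classify.method,
            "classify_alpha": self.classify.alpha,
            "classify_lambda_grid_size": self.classify.lambda_grid_size,
            "classify_inner_folds": self.classify.inner_folds,
            "contrast": f"{self.contrast[0]}:{self.contrast[1]}",
            "bins": ",".join(f"{lo}-{hi}" for lo, hi in self.bins),
            "seed": self.seed,
        }

    @classmethod
    def from_flat_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs: dict = {}
        mse_kwargs = {}
        for src, dst in (("mse_m", "m"), ("mse_r_frac", "r_frac"), ("mse_max_scale", "max_scale")):
            if src in d:
                mse_kwargs[dst] = type(SampEnParams.__dataclass_fields__[dst].default)(d[src])
        kwargs["mse"] = SampEnParams(**mse_kwargs)
        cls_kwargs = {}
        for src, dst in (
            ("classify_method", "method"),
            ("classify_alpha", "alpha"),
            ("classify_lambda_grid_size", "lambda_grid_size"),
            ("classify_inner_folds", "inner_folds"),
        ):
            if src in d:
                cls_kwargs[dst] = d[src]
        if "alpha" in cls_kwargs:
            cls_kwargs["alpha"] = float(cls_kwargs["alpha"])
        for key in ("lambda_grid_size", "inner_folds"):
            if key in cls_kwargs:
                cls_kwargs[key] = int(cls_kwargs[key])
        kwargs["classify"] = ClassifyConfig(**cls_kwargs)
        if "contrast" in d:
            kwargs["contrast"] = tuple(str(d["contrast"]).split(":"))
        if "bins" in d:
            kwargs["bins"] = tuple(
                tuple(int(v) for v in part.split("-"))
                for part in str(d["bins"]).split(",")
            )
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} is not a key-value mapping")
        return cls.from_flat_dict(d)
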