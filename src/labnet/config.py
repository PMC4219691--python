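"""Pipeline configuration with YAML round-trip support."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .exceptions import ValidationError

__all__ = ["PipelineConfig"]

SYMMETRISE_RULES = ("or", "and", "mean", "max", "min")

# The empirical-null gate needs enough permutations for the counter
# distribution to have support.
MIN_PERMUTATIONS_FOR_GATE = 20


@dataclass
class PipelineConfig:
    """All tunable parameters of the inference pipeline.

    Defaults reproduce the reference benchmark settings: 3-fold
    cross-validation on 10% of genes for the shrinkage factor, the best 80%
    of step-1 coefficients carried into the permutation stage, fanout 1, up
    to 500 permutations, OR symmetrisation.
    """

    cv_folds: int = 3
    lambda_subset_fraction: float = 0.10
    grid_size: int = 100
    best_fraction: float = 0.80
    fanout: int = 1
    permutations: int = 500
    significance_level: float = 0.05
    gate_enabled: bool = True
    symmetrise_rule: str = "or"
    seed: int = 0
    workers: int = 1
    lam: float | None = None  # fixed shrinkage factor; None -> estimate by CV

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not 0 < self.lambda_subset_fraction <= 1:
            raise ValidationError("lambda_subset_fraction must be in (0, 1]")
        if self.grid_size < 2:
            raise ValidationError("grid_size must be >= 2")
        if not 0 < self.best_fraction <= 1:
            raise ValidationError("best_fraction must be in (0, 1]")
        if self.fanout < 1:
            raise ValidationError("fanout must be >= 1")
        if self.permutations < 0:
            raise ValidationError("permutations must be >= 0")
        if not 0 < self.significance_level < 1:
            raise ValidationError("significance_level must be in (0, 1)")
        if self.symmetrise_rule not in SYMMETRISE_RULES:
            raise ValidationError(
                f"symmetrise_rule must be one of {SYMMETRISE_RULES}, "
                f"got {self.symmetrise_rule!r}"
            )
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")
        if self.lam is not None and self.lam <= 0:
            raise ValidationError("lam must be > 0 when given")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
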