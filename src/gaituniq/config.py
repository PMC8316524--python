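"""Run configuration: one file drives the whole simulate→verify pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import CohortParams
from .verification import METHODS


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configurations."""


@dataclass
class RunConfig:
    """Stage parameters for a full analysis run.

    Every random stage carries an explicit seed: the cohort generator
    (``cohort.seed``), the different-pair subsample (``pair_seed``) and the
    cross-validation fold shuffle (``cv_seed``).
    """

    cohort: CohortParams = field(default_factory=CohortParams)
    side: str = "right"
    frames: int = 101
    pca_k: int | None = 30          # feature dimension; or use pca_variance
    pca_variance: float | None = None
    methods: tuple = METHODS
    folds: int = 5
    pair_seed: int | None = None
    cv_seed: int | None = None
    population: int = 10            # population size for uniqueness estimates

    def validate(self) -> None:
        self.cohort.validate()
        if self.side not in ("left", "right"):
            raise ConfigError(f"side must be left|right, got {self.side!r}")
        if self.frames < 2:
            raise ConfigError("frames must be >= 2")
        if (self.pca_k is None) == (self.pca_variance is None):
            raise ConfigError("exactly one of pca_k / pca_variance must be set")
        if self.pca_variance is not None and not 0 < self.pca_variance <= 1:
            raise ConfigError("pca_variance must be in (0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        for name in ("pair_seed", "cv_seed"):
            if getattr(self, name) is None:
                raise ConfigError(f"{name} must be set (every random stage needs a seed)")
        if self.cohort.seed is None:
            raise ConfigError("cohort.seed must be set")
        if self.population < 1:
            raise ConfigError("population must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        cfg = cls(cohort=CohortParams(**cohort), **d)
        cfg.methods = tuple(cfg.methods)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
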