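"""Analysis configuration.

Houses the constants of the pipeline: the Tukey fence multiplier (1.5 x IQR),
the quantile rule used for both fences and quartile breakpoints, the IRLS
controls of the logistic fit and its multiplicity adjustment, the cost matrix
and fold count of the threshold search, and the binomial CI method.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class GlmConfig:
    tolerance: float = 1e-8
    max_iterations: int = 25
    adjust_method: str = "tukey"  # tukey | bonferroni | holm | none

    def validate(self) -> None:
        if self.tolerance <= 0:
            raise ConfigError("glm.tolerance must be positive")
        if self.max_iterations < 1:
            raise ConfigError("glm.max_iterations must be >= 1")
        if self.adjust_method not in {"tukey", "bonferroni", "holm", "none"}:
            raise ConfigError(f"unknown adjust_method {self.adjust_method!r}")


@dataclass
class CartConfig:
    """Cost-sensitive stump + cross-validation controls.

    A missed death (false negative) costs ``fn_cost`` relative to a false
    alarm at ``fp_cost``; the 10:1 default makes the rare deaths drive the
    split despite the class imbalance.
    """

    fn_cost: float = 10.0
    fp_cost: float = 1.0
    n_folds: int = 10
    min_leaf: int = 7
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.fn_cost <= 0 or self.fp_cost <= 0:
            raise ConfigError("fn_cost and fp_cost must be strictly positive")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be >= 1")


@dataclass
class AnalysisConfig:
    iqr_multiplier: float = 1.5
    quantile_rule: str = "linear"  # numpy quantile method ("type 7")
    glm: GlmConfig = field(default_factory=GlmConfig)
    cart: CartConfig = field(default_factory=CartConfig)
    ci_method: str = "wald"  # wald | wilson
    alpha: float = 0.05

    def validate(self) -> "AnalysisConfig":
        if self.iqr_multiplier <= 0:
            raise ConfigError("iqr_multiplier must be strictly positive")
        if self.ci_method not in {"wald", "wilson"}:
            raise ConfigError(f"unknown ci_method {self.ci_method!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        self.glm.validate()
        self.cart.validate()
        return self

    # -- flat key-value serialization -------------------------------------

    def to_flat_dict(self) -> dict:
        flat: dict[str, object] = {}

        def walk(prefix: str, obj) -> None:
            for f in dataclasses.fields(obj):
                value = getattr(obj, f.name)
                key = f"{prefix}{f.name}"
                if dataclasses.is_dataclass(value):
                    walk(key + ".", value)
                else:
                    flat[key] = value

        walk("", self)
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "AnalysisConfig":
        cfg = cls()
        for key, value in flat.items():
            obj = cfg
            *parents, leaf = key.split(".")
            for part in parents:
                if not hasattr(obj, part):
                    raise ConfigError(f"unknown config section {part!r} in {key!r}")
                obj = getattr(obj, part)
            if not hasattr(obj, leaf):
                raise ConfigError(f"unknown config key {key!r}")
            setattr(obj, leaf, value)
        return cfg.validate()

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat YAML key-value file (dotted keys address nested
        fields, e.g. ``cart.fn_cost: 10``); nested mappings are accepted too."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a key-value mapping")
        flat: dict[str, object] = {}

        def flatten(prefix: str, obj) -> None:
            for k, v in obj.items():
                if isinstance(v, dict):
                    flatten(f"{prefix}{k}.", v)
                else:
                    flat[f"{prefix}{k}"] = v

        flatten("", raw)
        return cls.from_flat_dict(flat)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_flat_dict(), sort_keys=True), encoding="utf-8"
        )
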