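"""Run configuration: every stage parameter in one validated, serialisable
object.  Seeds are always explicit — a config without a seed is refused."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .lasso import DEFAULT_LAMBDA_GRID


@dataclass
class RunConfig:
    seed: int
    n_respondents: int = 680
    target_prevalence: float = 0.226
    screen_threshold: float = 0.5
    #: penalty used by the Lasso feature-selection stage; the definitive
    #: model stage always grid-searches `lambda_grid`
    selection_lambda: float | None = 10.0
    lambda_grid: list = field(default_factory=lambda: list(DEFAULT_LAMBDA_GRID))
    n_repeats: int = 20
    n_folds: int = 3
    split_fractions: tuple = (0.6, 0.2, 0.2)
    ci_family_level: float = 0.90
    ci_method: str = "normal"  # or "quantile"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.seed is None or not isinstance(self.seed, int):
            raise ValueError("config must declare an explicit integer seed")
        if not 0 < self.screen_threshold < 1:
            raise ValueError("screen_threshold must lie in (0, 1)")
        if self.selection_lambda is not None and self.selection_lambda < 0:
            raise ValueError("selection_lambda must be >= 0 (or null for grid search)")
        if not self.lambda_grid:
            raise ValueError("lambda_grid must be non-empty")
        if self.ci_method not in ("normal", "quantile"):
            raise ValueError("ci_method must be 'normal' or 'quantile'")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.canonical(), sort_keys=True))

    def canonical(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["lambda_grid"] = [float(v) for v in self.lambda_grid]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.canonical(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError("config must declare an explicit integer seed")
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)
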