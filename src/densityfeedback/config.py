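"""Declarative run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .life_history import LifeHistoryConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything that determines a study run.

    The effective configuration is written next to each run's outputs so a
    run can be reproduced from its manifest alone.
    """

    species: list[str] | None = None        # None = all 21
    scenarios: list[str] = field(default_factory=lambda: ["i", "ii", "ix"])
    n_reps: int = 100
    seed: int = 0
    horizon_generations: float = 40.0
    c_grid: list[float] = field(default_factory=lambda: [1.5, 2.0, 3.0])
    sd_survival: float = 0.05
    sd_fertility: float = 0.05
    juvenile_sd_multiplier: float = 1.0
    fertility_split: float = 0.0             # 0 = survival-only feedback
    catastrophe_hits_recruitment: bool = False
    k_fluctuation_catastrophes: bool = True   # Table-3 reading: catastrophes on
    integerize_abundance: bool = False
    n0_convention: str = "simplified"         # simplified | literal
    min_transitions: int = 30
    feedback_tol: float = 0.005
    harvest_tol: float = 0.003
    null_catastrophe_tol: float = 0.005
    output_dir: str = "results"
    life_history: LifeHistoryConfig = field(default_factory=LifeHistoryConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        lh = d.pop("life_history", None)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if lh is not None:
            lh = dict(lh)
            if "adult_survival_bounds" in lh:
                lh["adult_survival_bounds"] = tuple(lh["adult_survival_bounds"])
            cfg.life_history = LifeHistoryConfig(**lh)
        return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["life_history"]["adult_survival_bounds"] = list(
        d["life_history"]["adult_survival_bounds"]
    )
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
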