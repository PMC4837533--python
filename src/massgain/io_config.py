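"""Experiment configuration (YAML) and deterministic CSV serialization."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .genetic_model import DEFAULT_V_P, H_LEVELS, P_LEVELS

VALID_POPULATIONS = ("three_genotype", "nine_genotype")
VALID_DOMINANCE = ("none", "partial", "complete")

#: Seedlings per class must be integral: population kind -> divisor of N.
_N_DIVISORS = {"three_genotype": 4, "nine_genotype": 16}


@dataclass
class ExperimentConfig:
    """Run settings; defaults reproduce the full study design."""

    V_P: float = DEFAULT_V_P
    H_levels: tuple[float, ...] = H_LEVELS
    P_levels: tuple[float, ...] = P_LEVELS
    N: int = 400
    n_reps: int = 1000
    populations: tuple[str, ...] = VALID_POPULATIONS
    dominance_cases: tuple[str, ...] = VALID_DOMINANCE
    grid_step: float = 0.05
    root_seed: int = 0
    out_dir: str = "results"


def validate_config(config: ExperimentConfig) -> ExperimentConfig:
    """Check every field; raises ValueError naming the offending field."""
    if not config.V_P > 0:
        raise ValueError(f"V_P: must be positive, got {config.V_P}")
    for name, levels in (("H_levels", config.H_levels), ("P_levels", config.P_levels)):
        if not levels:
            raise ValueError(f"{name}: must be non-empty")
        for level in levels:
            if not 0 < level <= 1:
                raise ValueError(f"{name}: level {level} outside (0, 1]")
    if config.N < 1:
        raise ValueError(f"N: must be at least 1, got {config.N}")
    if config.n_reps < 1:
        raise ValueError(f"n_reps: must be at least 1, got {config.n_reps}")
    if not config.populations:
        raise ValueError("populations: must be non-empty")
    for pop in config.populations:
        if pop not in VALID_POPULATIONS:
            raise ValueError(f"populations: unknown population {pop!r}")
        divisor = _N_DIVISORS[pop]
        if config.N % divisor:
            raise ValueError(
                f"N: {config.N} is not a multiple of {divisor}, so the "
                f"{pop} class counts are not integral"
            )
    if not config.dominance_cases:
        raise ValueError("dominance_cases: must be non-empty")
    for dom in config.dominance_cases:
        if dom not in VALID_DOMINANCE:
            raise ValueError(f"dominance_cases: unknown case {dom!r}")
    denominator = round(1.0 / config.grid_step)
    if denominator < 2 or abs(denominator * config.grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step: {config.grid_step} does not divide 1 evenly")
    return config


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load a YAML config; missing file content or fields fall back to defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    for name in ("H_levels", "P_levels", "populations", "dominance_cases"):
        if name in raw:
            raw[name] = tuple(raw[name])
    return validate_config(ExperimentConfig(**raw))


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic RFC-4180 CSV with fixed column order and LF line ends.

    Floats use pandas' shortest round-trip representation, so a
    write-then-read cycle reproduces the records exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
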