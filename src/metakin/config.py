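"""Run configuration: flat INI-style ``key = value`` sections.

A :class:`RunConfig` collects every tunable constant of the pipeline
(thresholds, bootstrap and ML settings, the master seed) with the
defaults used throughout; :func:`load_config` parses a config file and
rejects unknown sections or keys outright.
"""
from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import List, Union

from .constants import DEFAULT_TEMPERATURE, DEFAULT_Z_THRESHOLD
from .exceptions import InvalidParameterError, ValidationError
from .features import MODEL_SET

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # [physics]
    temperature: float = DEFAULT_TEMPERATURE  # K
    z_threshold: float = DEFAULT_Z_THRESHOLD  # angstrom

    # [kinetics]
    ks_threshold: float = 0.05
    ks_n_random: int = 1_000_000
    n_boot: int = 10_000
    bootstrap_size: int = 15

    # [filtering]
    magnitude_cutoff: float = 1.0  # kcal/mol
    spread_cutoff: float = 0.25  # kcal/mol

    # [augmentation]
    block_size: int = 100
    n_aug_per_ligand: int = 200

    # [ml]
    test_size: float = 0.2
    cv_folds: int = 10
    n_trials: int = 100
    top_k: int = 15
    model_set: List[str] = field(default_factory=lambda: list(MODEL_SET))
    tune: bool = True

    # [seeds]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature", "z_threshold", "ks_threshold",
                     "magnitude_cutoff", "spread_cutoff", "test_size"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("ks_n_random", "n_boot", "bootstrap_size", "block_size",
                     "n_aug_per_ligand", "cv_folds", "n_trials", "top_k"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        unknown = set(self.model_set) - set(MODEL_SET)
        if unknown:
            raise InvalidParameterError(f"unknown models: {sorted(unknown)}")


_SECTIONS = {
    "physics": ("temperature", "z_threshold"),
    "kinetics": ("ks_threshold", "ks_n_random", "n_boot", "bootstrap_size"),
    "filtering": ("magnitude_cutoff", "spread_cutoff"),
    "augmentation": ("block_size", "n_aug_per_ligand"),
    "ml": ("test_size", "cv_folds", "n_trials", "top_k", "model_set", "tune"),
    "seeds": ("seed",),
}


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse an INI config file into a :class:`RunConfig`.

    Unknown sections or keys raise :class:`ValidationError`.
    """
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise ValidationError(f"config file not found: {path}")
    kwargs = {}
    types = {f.name: f.type for f in dc_fields(RunConfig)}
    for section in parser.sections():
        if section not in _SECTIONS:
            raise ValidationError(f"unknown config section [{section}]")
        for key, value in parser[section].items():
            if key not in _SECTIONS[section]:
                raise ValidationError(f"unknown key {key!r} in section [{section}]")
            if key == "model_set":
                kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
            elif key == "tune":
                kwargs[key] = parser[section].getboolean(key)
            elif types[key] == "int" or key in (
                "ks_n_random", "n_boot", "bootstrap_size", "block_size",
                "n_aug_per_ligand", "cv_folds", "n_trials", "top_k", "seed",
            ):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
    return RunConfig(**kwargs)
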