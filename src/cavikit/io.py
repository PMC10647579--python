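"""Cohort CSV round-tripping and run configuration.

The cohort file format is a plain comma-separated table, UTF-8, "."
decimal, lowercase snake_case headers, in the fixed column order of
:data:`cavikit.cohort.COHORT_COLUMNS`; numbers are written with six
significant digits so repeated writes are byte-identical and diffable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    COHORT_COLUMNS,
    GeneratorConfig,
    InteractionCoefficients,
    NoiseSpec,
    StratumPair,
)
from .errors import ConfigError, SchemaError
from .hemodynamics import HemoConstants

__all__ = ["read_cohort_csv", "write_cohort_csv", "RunConfig"]

REQUIRED_COLUMNS = ["id", "age", "sex", "sbp", "dbp"]
INT_COLUMNS = {"id", "hypertension", "diabetes", "dyslipidemia", "smoking"}


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical order and formatting."""
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    out = table[cols]
    out.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def read_cohort_csv(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` naming any missing required column.
    Rows violating SBP > DBP > 0 are rejected; with ``strict`` the
    error message lists their file line numbers, otherwise they are
    dropped silently.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in table.columns:
        if col in INT_COLUMNS:
            table[col] = table[col].astype(int)
        elif col != "sex":
            table[col] = table[col].astype(float)
    bad = ~((table["dbp"] > 0) & (table["sbp"] > table["dbp"]))
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        lines = (table.index[bad] + 2).tolist()
        if strict:
            raise SchemaError(
                f"{path.name}: rows with sbp <= dbp or non-positive pressures "
                f"at line(s) {lines}"
            )
        table = table[~bad].reset_index(drop=True)
    return table


@dataclass
class RunConfig:
    """Everything needed for one reproducible generation + analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    threshold_age: float = 70.0
    permutations: int = 999
    permutation_seed: int = 0
    extra_terms: tuple[str, ...] = ()
    prediction_ages: tuple[float, ...] = (40, 50, 60, 70, 80, 90)
    out_dir: str = "cavikit_run"

    def validate(self) -> None:
        self.generator.validate()
        if self.permutations < 99:
            raise ConfigError("permutations must be at least 99")
        if self.threshold_age <= 0:
            raise ConfigError("threshold_age must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        if isinstance(gen, dict):
            gen = _generator_from_dict(gen)
        cfg = cls(generator=gen, **_coerce_tuples(data))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)


def _coerce_tuples(data: dict) -> dict:
    for key in ("extra_terms", "prediction_ages"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return data


_PAIR_FIELDS = {
    f.name for f in dataclasses.fields(GeneratorConfig)
    if f.type == "StratumPair"
}


def _generator_from_dict(data: dict) -> GeneratorConfig:
    kwargs = dict(data)
    for key, value in list(kwargs.items()):
        if key in _PAIR_FIELDS and isinstance(value, (list, tuple, dict)):
            kwargs[key] = (
                StratumPair(**value) if isinstance(value, dict)
                else StratumPair(*value)
            )
        elif key in ("age_range", "dbp_range") and isinstance(value, list):
            kwargs[key] = tuple(value)
        elif key in ("cavi0_coefficients", "cavi_coefficients") and isinstance(value, (dict, list)):
            kwargs[key] = (
                InteractionCoefficients(**value) if isinstance(value, dict)
                else InteractionCoefficients(*value)
            )
        elif key in ("cavi0_noise", "cavi_noise") and isinstance(value, dict):
            kwargs[key] = NoiseSpec(**value)
        elif key == "hemo" and isinstance(value, dict):
            kwargs[key] = HemoConstants(**value)
    try:
        cfg = GeneratorConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid generator config: {exc}") from exc
    cfg.validate()
    return cfg


def _plain(obj):
    """Recursively convert dataclass dicts/NumPy scalars to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
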