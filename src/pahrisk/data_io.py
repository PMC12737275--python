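"""Readers and writers for concentration/uncertainty tables, configs and reports.

All tables are plain CSV (UTF-8, "." decimal separator).  A concentration
table has columns ``sample_id``, ``species`` and the 16 congener
abbreviations in registry order; values are µg/kg wet weight.  An
uncertainty table has the same congener columns (plus ``sample_id``) and
holds strictly positive measurement uncertainties in the same units, used to
weight the PMF objective.

Unit conventions are centralized here: concentrations are exchanged in µg/kg
wet weight and intake rates in g·person⁻¹·day⁻¹; the risk equations work in
mg/kg and kg/day, so both carry a single ×10⁻³ conversion applied through
:data:`UG_PER_KG_TO_MG_PER_KG` and :data:`G_PER_DAY_TO_KG_PER_DAY` (and
nowhere else, to prevent double conversion).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import registry as _registry

__all__ = [
    "ConcentrationMatrix",
    "UncertaintyMatrix",
    "read_concentrations",
    "write_concentrations",
    "read_uncertainties",
    "write_uncertainties",
    "write_report",
    "load_config",
    "save_config",
    "config_hash",
    "SPECIES",
    "UG_PER_KG_TO_MG_PER_KG",
    "G_PER_DAY_TO_KG_PER_DAY",
]

SPECIES = ("crucian_carp", "common_carp", "yellow_catfish", "crayfish")

# the only unit conversions in the package (see module docstring)
UG_PER_KG_TO_MG_PER_KG = 1e-3
G_PER_DAY_TO_KG_PER_DAY = 1e-3


@dataclass
class ConcentrationMatrix:
    """n samples × 16 congeners of PAH concentrations, µg/kg wet weight."""

    sample_ids: list[str]
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, _registry.N_CONGENERS):
            raise ValueError(
                f"values must be ({n}, {_registry.N_CONGENERS}), got {self.values.shape}")
        if len(self.species) != n:
            raise ValueError("one species label per sample required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_id in concentration matrix")
        unknown = sorted(set(self.species) - set(SPECIES))
        if unknown:
            raise ValueError(f"unknown species {unknown}; allowed: {list(SPECIES)}")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite concentration value")
        if np.any(self.values < 0):
            raise ValueError("negative concentration value")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=_registry.abbreviations())
        df.insert(0, "species", self.species)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationMatrix":
        abbrs = _registry.abbreviations()
        missing = [c for c in ["sample_id", "species", *abbrs] if c not in df.columns]
        if missing:
            raise ValueError(f"concentration table missing columns: {missing}")
        values = df[abbrs].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            bad = [abbrs[j] for j in sorted(set(np.argwhere(np.isnan(values))[:, 1]))]
            raise ValueError(f"non-numeric concentration value in columns {bad}")
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            species=[str(s) for s in df["species"]],
            values=values,
        )


@dataclass
class UncertaintyMatrix:
    """Per-cell measurement uncertainties paired with a ConcentrationMatrix."""

    values: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != _registry.N_CONGENERS:
            raise ValueError(f"values must be (n, {_registry.N_CONGENERS})")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("uncertainties must be finite and strictly positive")

    def matches(self, conc: ConcentrationMatrix) -> bool:
        return self.values.shape == conc.values.shape


def read_concentrations(path: str | Path) -> ConcentrationMatrix:
    """Read and validate a concentration CSV (see module docstring for layout)."""
    df = pd.read_csv(path, comment="#")
    return ConcentrationMatrix.from_frame(df)


def write_concentrations(matrix: ConcentrationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False)


def read_uncertainties(path: str | Path) -> UncertaintyMatrix:
    df = pd.read_csv(path, comment="#")
    abbrs = _registry.abbreviations()
    missing = [c for c in abbrs if c not in df.columns]
    if missing:
        raise ValueError(f"uncertainty table missing columns: {missing}")
    ids = [str(s) for s in df["sample_id"]] if "sample_id" in df.columns else None
    return UncertaintyMatrix(values=df[abbrs].to_numpy(dtype=float), sample_ids=ids)


def write_uncertainties(unc: UncertaintyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(unc.values, columns=_registry.abbreviations())
    if unc.sample_ids is not None:
        df.insert(0, "sample_id", unc.sample_ids)
    df.to_csv(path, index=False)


def write_report(results: pd.DataFrame, path: str | Path, *,
                 seed: int | None = None,
                 config: Mapping[str, Any] | None = None,
                 stage: str | None = None,
                 timestamp: bool = True) -> None:
    """Write a stage output table with a commented run-metadata header.

    Data rows are byte-identical across runs with the same inputs and seed;
    only the metadata block carries the (optional) timestamp.
    """
    path = Path(path)
    lines = []
    if stage is not None:
        lines.append(f"# stage: {stage}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if timestamp:
        lines.append(f"# written: {datetime.now(timezone.utc).isoformat()}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in lines:
            fh.write(line + "\n")
        results.to_csv(fh, index=False)


def load_config(path: str | Path) -> dict:
    """Load a nested key-value run configuration (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def substitute_below_loq(matrix: ConcentrationMatrix, loq: Sequence[float],
                         flags: np.ndarray | None = None) -> ConcentrationMatrix:
    """Optionally replace flagged non-detects with LOQ/2.

    By default values below the limit of quantification are accepted as-is
    (all 16 congeners were quantified in every survey sample); this helper
    implements the conventional LOQ/2 substitution when ``flags`` marks cells
    as non-detects.
    """
    loq = np.asarray(loq, dtype=float)
    values = matrix.values.copy()
    if flags is not None:
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != values.shape:
            raise ValueError("flags shape must match values")
        values[flags] = np.broadcast_to(loq / 2.0, values.shape)[flags]
    return ConcentrationMatrix(matrix.sample_ids, matrix.species, values)
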