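"""Delimited-table readers/writers and run configuration.

All tables are CSV (UTF-8, header row) with the site or species
identifier in the first column.  The community reader validates strict
binarity and reports offending cells; trait tables may arrive either
raw (continuous wing span / voltinism) or already binned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trait_space import RAW_TRAIT_COLUMNS, bin_continuous_traits, validate_trait_table

__all__ = [
    "read_community",
    "read_traits",
    "read_environment",
    "write_community",
    "RunConfig",
]


class TableFormatError(ValueError):
    """An input table violates its format contract."""


def _read_indexed(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: need an id column plus data columns")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise TableFormatError(f"{path}: duplicate identifier {dup!r}")
    return df


def read_community(path) -> pd.DataFrame:
    """Read and validate a binary sites × species matrix."""
    df = _read_indexed(path)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableFormatError(f"{path}: duplicate species column {dup!r}")
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = ~vals.isin([0, 1]) | vals.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-binary value {df.iloc[i, j]!r} at site {df.index[i]!r}, "
            f"species {df.columns[j]!r}"
        )
    return vals.astype(np.int8)


def write_community(community: pd.DataFrame, path) -> None:
    community.rename_axis("site").to_csv(path)


def read_traits(path) -> pd.DataFrame:
    """Read a trait table, binning continuous columns when present."""
    df = _read_indexed(path)
    if "wing_span" in df.columns:  # raw continuous traits
        missing = [c for c in RAW_TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: raw trait table lacks columns {missing}")
        df = df.copy()
        df["wing_span"] = pd.to_numeric(df["wing_span"])
        df["voltinism"] = pd.to_numeric(df["voltinism"])
        return bin_continuous_traits(df)
    return validate_trait_table(df)


def read_environment(path) -> pd.DataFrame:
    """Read the per-site environment table."""
    df = _read_indexed(path)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        col = num.columns[num.isna().any()][0]
        raise TableFormatError(f"{path}: non-numeric value in column {col!r}")
    for coord in ("x", "y"):
        if coord not in num.columns:
            raise TableFormatError(f"{path}: missing coordinate column {coord!r}")
        if not np.isfinite(num[coord]).all():
            raise TableFormatError(f"{path}: non-finite coordinate in {coord!r}")
    return num


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    community: str
    traits: str
    environment: str
    out_dir: str
    m_axes: int = 3
    beta_axes: int = 2
    min_species: int = 5
    n_randomizations: int = 199
    vif_threshold: float = 10.0
    gdm_pair_cap: int = 50_000
    seed: int = 0
    gam_responses: tuple[str, ...] = ("S", "FRic", "FR", "FV")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.community, self.traits, self.environment):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.m_axes <= 0 or self.vif_threshold <= 0 or self.n_randomizations < 2:
            raise ValueError("thresholds and counts must be positive")
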