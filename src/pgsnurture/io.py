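"""Trio-table and configuration file handling.

Trio tables are tab-separated text with the fixed header
``fam_id  T_p  NT_p  T_m  NT_m  Y_o  Y_p  Y_m``; parental phenotypes may
be NA.  Numbers are serialized with 17 significant digits so that a
write→read round trip is loss-free.  Simulation configurations are flat
``key: value`` YAML files validated against :class:`~pgsnurture.sim.SimConfig`
(unknown keys are rejected fail-fast).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .sim import SimConfig, TRIO_COLUMNS

__all__ = ["read_trio_table", "write_trio_table", "load_config",
           "TrioFormatError", "ConfigError"]


class TrioFormatError(ValueError):
    pass


class ConfigError(ValueError):
    pass


_REQUIRED = [c for c in TRIO_COLUMNS if c not in ("Y_p", "Y_m")]


def write_trio_table(trios: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trio table as TSV with full-precision floats and NA for
    missing parental phenotypes."""
    trios.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.17g")


def read_trio_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trio table, enforcing the documented column contract.

    All score columns and the offspring phenotype must be complete and
    numeric; NA is allowed only in Y_p / Y_m.  Errors name the offending
    column (and the first offending row for non-numeric cells).
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"],
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TrioFormatError(f"cannot parse {path}: {exc}") from exc
    for col in TRIO_COLUMNS:
        if col not in df.columns:
            raise TrioFormatError(f"missing required column: {col}")
    for col in TRIO_COLUMNS[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TrioFormatError(
                f"non-numeric value in column {col} at row {row}"
            )
        df[col] = coerced
    for col in _REQUIRED[1:]:
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna())[0])
            raise TrioFormatError(
                f"column {col} contains NA at row {row}; NA is allowed "
                "only in Y_p and Y_m"
            )
    return df[TRIO_COLUMNS]


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def load_config(path: Union[str, Path, None]) -> SimConfig:
    """Simulation configuration from a flat YAML file.

    An empty (or absent) file yields the central study condition defaults
    (h2_t0=.5, r2_pgs_t0=.05, vf_t0=.15, r_mate=.25, m=100, n_fam=16000,
    generations=20).  Unknown keys and invalid values raise
    :class:`ConfigError` naming the problem.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected flat key-value mappings")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    try:
        return SimConfig(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
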