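"""Strict CSV schemas and validated readers for the pipeline's tables."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "CALCIFICATION_COLUMNS",
    "SURVIVORSHIP_COLUMNS",
    "SchemaError",
    "read_calcification",
    "read_survivorship",
    "file_sha256",
]

CALCIFICATION_COLUMNS = [
    "species", "genet", "ramet_id", "site", "treatment", "temp_level",
    "ph_level", "header_tank", "mesocosm", "w_initial_g", "w_final_g",
    "days", "alive",
]
SURVIVORSHIP_COLUMNS = ["species", "era_year", "dhw", "n_exposed", "n_dead"]


class SchemaError(ValueError):
    """A CSV does not match its declared column schema."""


def _validate(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; expected exactly "
            f"{columns}")
    return df[columns]


def read_calcification(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _validate(df, CALCIFICATION_COLUMNS, path)
    bad = df["w_initial_g"] <= 0
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"{path}: row {row}, column w_initial_g must be > 0")
    return df


def read_survivorship(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _validate(df, SURVIVORSHIP_COLUMNS, path)
    bad = df["n_dead"] > df["n_exposed"]
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"{path}: row {row}, column n_dead exceeds n_exposed")
    return df


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
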