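"""CSV/JSON I/O with strict schema validation.

All artifacts are plain CSV (low-rate tabular measurements) plus a JSON run
manifest carrying the seed, a configuration hash and per-stage record
counts, so that any run can be reproduced and audited.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from pepstress.config import PipelineConfig
from pepstress.cohort import (
    BEAT_COLUMNS,
    CUFF_COLUMNS,
    MEASUREMENT_COLUMNS,
    SUBJECT_COLUMNS,
)
from pepstress.protocol import PHASES


class SchemaError(ValueError):
    """A table failed schema validation."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.columns.duplicated().any() or any(str(c).startswith("Unnamed") for c in df.columns) \
            or list(df.columns) != list(dict.fromkeys(df.columns)):
        raise SchemaError(f"{path}: duplicated or malformed header at line 1")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table.

    Checks the required columns, the controlled phase vocabulary (rest,
    tsst_Q1..Q8, ergo_E1..E10, ergo_B1..B6, final_rest) and numeric PEP
    values, naming the offending file and first bad line on failure.
    """
    path = Path(path)
    df = _read_csv(path, MEASUREMENT_COLUMNS)
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise SchemaError(f"{path}: line {line}: phase {df.loc[bad, 'phase'].iloc[0]!r} "
                          f"not in controlled vocabulary")
    pep = pd.to_numeric(df["pep_ms"], errors="coerce")
    if pep.isna().any():
        line = int(df.index[pep.isna()][0]) + 2
        raise SchemaError(f"{path}: line {line}: non-numeric pep_ms value")
    df["pep_ms"] = pep
    df["valid"] = df["valid"].astype(bool)
    return df


def write_measurement_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, SUBJECT_COLUMNS)


def read_beat_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, BEAT_COLUMNS)


def read_cuff_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, CUFF_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline configuration from YAML/JSON (defaults when absent);
    unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
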