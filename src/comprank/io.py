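"""Validated CSV table I/O (RFC-4180, UTF-8, header row).

Each table the pipeline reads or writes has a declared schema: required
columns with types and an optional key whose combinations must be
unique. Row-level parse failures are collected with line numbers and
reported together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "TableSchema", "SCHEMAS", "read_table", "write_table"]


class SchemaError(ValueError):
    """A table failed schema validation."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict  # column -> numpy/pandas dtype to coerce to
    key: tuple = ()  # columns whose combinations must be unique
    non_negative: tuple = ()


SCHEMAS: dict[str, TableSchema] = {
    "units": TableSchema(
        "units",
        {
            "unit_id": str,
            "group_id": str,
            "tp_latency_ms": float,
            "half_width_ms": float,
            "auc": float,
            "doublet_prob": float,
        },
        key=("unit_id",),
        non_negative=("tp_latency_ms", "half_width_ms", "auc"),
    ),
    "waveforms": TableSchema(
        "waveforms",
        {"unit_id": str, "sample_idx": int, "amplitude_uv": float},
        key=("unit_id", "sample_idx"),
    ),
    "spikes": TableSchema(
        "spikes", {"unit_id": str, "spike_time_s": float}
    ),
    "trials": TableSchema(
        "trials",
        {
            "group_id": str,
            "day": int,
            "session_id": str,
            "pair_id": str,
            "trial_idx": int,
            "subject_id": str,
            "opponent_id": str,
            "start_area": str,
            "t_gate_open_s": float,
            "t_exit_sa_s": float,
            "t_reach_rz_s": float,
            "pellet_winner_id": str,
            "opponent_relative_rank": str,
        },
        key=("group_id", "day", "pair_id", "trial_idx", "subject_id"),
    ),
    "tube": TableSchema(
        "tube",
        {
            "group_id": str,
            "day": int,
            "mouse_a": str,
            "mouse_b": str,
            "winner": str,
            "duration_s": float,
        },
        non_negative=("duration_s",),
    ),
    "warmspot": TableSchema(
        "warmspot",
        {"group_id": str, "day": int, "mouse_id": str, "occupancy_s": float},
        key=("group_id", "day", "mouse_id"),
        non_negative=("occupancy_s",),
    ),
    "truth": TableSchema(
        "truth",
        {"unit_id": str, "cell_type": str, "task_category": str},
        key=("unit_id",),
    ),
    "longitudinal_rates": TableSchema(
        "longitudinal_rates",
        {"day": int, "trial_idx": int, "category": str, "rate_hz": float},
        key=("day", "trial_idx", "category"),
        non_negative=("rate_hz",),
    ),
    "series": TableSchema(
        "series", {"label": str, "day": int, "value": float}, key=("label", "day")
    ),
}


def read_table(path: str, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate a CSV table against a schema.

    Raises SchemaError naming missing columns, unparsable cells (with
    1-based data line numbers), duplicate keys, or negative values in
    columns declared non-negative.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing columns {missing}")
    errors: list[str] = []
    out = {}
    for col, typ in schema.columns.items():
        raw = df[col]
        if typ is str:
            out[col] = raw
            continue
        coerced = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = coerced.isna() & (raw != "")
        for idx in df.index[bad][:10]:
            errors.append(
                f"{schema.name} line {idx + 2}: cannot parse {col}={raw[idx]!r}"
            )
        if typ is int and not bad.any():
            frac = coerced.dropna() % 1
            if (frac != 0).any():
                errors.append(f"{schema.name}: non-integer values in {col}")
            out[col] = coerced.astype("Int64")
        else:
            out[col] = coerced
    if errors:
        raise SchemaError("; ".join(errors))
    result = pd.DataFrame(out)[list(schema.columns)]
    if schema.key:
        dup = result.duplicated(subset=list(schema.key))
        if dup.any():
            raise SchemaError(
                f"{schema.name}: duplicate keys {list(schema.key)} at data line "
                f"{int(result.index[dup][0]) + 2}"
            )
    for col in schema.non_negative:
        if (result[col].dropna() < 0).any():
            raise SchemaError(f"{schema.name}: negative values in {col}")
    return result


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a table as RFC-4180 CSV with a header row (UTF-8)."""
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
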