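"""Tidy-CSV readers and writers shared by every pipeline stage.

One schema per domain table; reads validate column presence and dtypes and
report offending row numbers. Timestamps are ISO-8601, potentials MPa,
areas pixels; decimal parsing is locale-independent ("1.5" only).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "write_table", "read_table"]

# schema: {column: kind}; kind in {str, float, int, iso8601}
SCHEMAS: dict[str, dict] = {
    "area_series": {
        "plant_id": str,
        "treatment": str,
        "tissue": str,
        "timestamp": "iso8601",
        "age_days": float,
        "area_px": float,
    },
    "extracted_series": {
        "plant_id": str,
        "tissue": str,
        "timestamp": str,
        "raw_area_px": float,
        "relative_area": float,
    },
    "relative_series": {
        "plant_id": str,
        "tissue": str,
        "age_days": float,
        "relative_area": float,
    },
    "water_status": {
        "plant_id": str,
        "day": float,
        "treatment": str,
        "measure": str,
        "value": float,
        "pool_size": int,
    },
    "windows": {
        "plant_id": str,
        "tissue": str,
        "transition_type": str,
        "day": int,
        "t": float,
        "y": float,
    },
    "decline": {"day": float, "mean_stem_decline": float, "psi_x": float},
}

_CATEGORICAL = {
    "tissue": {"bud", "stem", "reference"},
    "treatment": {"W", "D"},
    "transition_type": {"dawn", "dusk"},
    "measure": {"psi_x", "pi_leaf", "pi_bud"},
}


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Write a tidy table, checking it satisfies the named schema first."""
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns for schema {schema!r}: {sorted(missing)}")
    out = df[list(cols)].copy()
    if "timestamp" in out.columns and np.issubdtype(out["timestamp"].dtype, np.datetime64):
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def _bad_rows(mask: pd.Series) -> str:
    rows = [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())[:10]]  # 1-based incl. header
    return f"rows {rows}"


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a tidy table; errors name the offending rows."""
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for col, kind in cols.items():
        raw = df[col]
        if kind in (float, int):
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & (raw != "")
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric values in column {col!r} at {_bad_rows(bad)}"
                )
            out[col] = converted.astype(float if kind is float else int)
        elif kind == "iso8601":
            converted = pd.to_datetime(raw, errors="coerce", format="ISO8601")
            bad = converted.isna()
            if bad.any():
                raise ValueError(
                    f"{path}: invalid ISO-8601 timestamps in {col!r} at {_bad_rows(bad)}"
                )
            out[col] = converted
        else:
            out[col] = raw
            if col in _CATEGORICAL:
                bad = ~raw.isin(_CATEGORICAL[col])
                if bad.any():
                    raise ValueError(
                        f"{path}: invalid {col!r} values at {_bad_rows(bad)}; "
                        f"expected one of {sorted(_CATEGORICAL[col])}"
                    )
    return pd.DataFrame(out)
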