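"""Report writing: fixed-column CSV and full-precision JSON outputs.

CSV cells are formatted through a per-column precision map so tables can be
compared against their conventional printed form (mixed 2-8 significant
figures); JSON always carries full floating precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["TABLE4_PRECISION", "format_cell", "write_report", "to_jsonable"]

# decimal places per column, matching the customary presentation of the
# a-priori success-rate table
TABLE4_PRECISION: Mapping[str, int] = {
    "gamma_pc": 8,
    "alpha_pc": 8,
    "beta_pc": 2,
    "fdr_pc": 8,
    "s_pc": 8,
    "tdr_pc": 8,
    "alpha_c": 2,
    "beta_c": 2,
    "fdr_c": 8,
    "tdr_c": 8,
    "s_c": 8,
    "s_o": 5,
}


def format_cell(value: Any, decimals: int | None) -> str:
    if decimals is None or not isinstance(value, (int, float, np.floating)):
        return str(value)
    return f"{float(value):.{decimals}f}".rstrip("0").rstrip(".") or "0"


def to_jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and dataclass-like values."""
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "__dataclass_fields__"):
        return {k: to_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_report(
    results: pd.DataFrame | dict,
    path: str | Path,
    fmt: str = "json",
    precision: Mapping[str, int] | None = None,
) -> Path:
    """Write results as CSV (formatted values) or JSON (full precision).

    DataFrames become row-record tables; a CSV keeps its column order and
    formats each numeric column to the precision map.  An empty DataFrame
    yields a header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(to_jsonable(results), indent=2) + "\n")
        return path
    if fmt != "csv":
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    if isinstance(results, dict):
        results = pd.DataFrame([results])
    precision = precision or {}
    formatted = results.copy()
    for col in formatted.columns:
        if col in precision:
            formatted[col] = [format_cell(v, precision[col]) for v in formatted[col]]
    formatted.to_csv(path, index=False)
    return path
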