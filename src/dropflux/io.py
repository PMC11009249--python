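"""Schema-validated CSV I/O for droplet trace sets and related tables.

All interchange is plain UTF-8 CSV with '.' decimals. The droplet trace
schema is fixed (see :data:`dropflux.synthetic.TRACE_COLUMNS`): one row per
(droplet_id, time_index) with a shared, strictly increasing time grid and a
constant per-droplet cell count.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .synthetic import TRACE_COLUMNS

__all__ = ["TraceValidationError", "validate_trace_table", "read_trace_table",
           "write_trace_table", "read_calibration_table",
           "write_calibration_table"]


class TraceValidationError(ValueError):
    """Droplet trace table violates the documented schema."""


def validate_trace_table(traces: pd.DataFrame) -> pd.DataFrame:
    """Validate the droplet trace schema, naming every offending column/row."""
    problems = []
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise TraceValidationError(f"missing columns: {missing}")
    value_cols = TRACE_COLUMNS[4:]
    bad = [c for c in value_cols
           if not np.all(np.isfinite(traces[c].to_numpy(dtype=float)))]
    if bad:
        problems.append(f"non-finite signals in columns {bad}")
    grids = traces.groupby("droplet_id")["time_s"].apply(
        lambda s: tuple(s.to_numpy())
    )
    if len(set(grids)) > 1:
        problems.append("droplets do not share a common time grid")
    grid = np.asarray(grids.iloc[0])
    if len(grid) < 2 or not np.all(np.diff(grid) > 0):
        problems.append("time grid is not strictly increasing")
    ncell_var = traces.groupby("droplet_id")["n_cells"].nunique()
    varying = ncell_var[ncell_var > 1]
    if len(varying):
        problems.append(
            f"n_cells varies within droplets {list(varying.index[:5])}"
        )
    if problems:
        raise TraceValidationError("; ".join(problems))
    return traces


def read_trace_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a droplet trace CSV."""
    traces = pd.read_csv(path)
    return validate_trace_table(traces)


def write_trace_table(traces: pd.DataFrame, path: Union[str, Path]) -> None:
    """Validate and write a droplet trace CSV (round-trip safe)."""
    validate_trace_table(traces)
    traces.to_csv(path, index=False)


def read_calibration_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"concentration", "signal"} - set(table.columns)
    if missing:
        raise TraceValidationError(
            f"calibration table missing columns: {sorted(missing)}"
        )
    return table


def write_calibration_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, index=False)
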