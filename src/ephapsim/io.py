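"""Delimited-text helpers for scalar time series.

The entropy pipeline accepts any single-column series or (time, value)
two-column file, comma- or whitespace-separated, with or without a one-line
header.  Only the last column is treated as the signal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_series", "write_series"]


def read_series(path) -> np.ndarray:
    """Load the value column of a delimited scalar series."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty series file")
    start = 0
    if _is_header(lines[0]):
        start = 1
    rows = [ln.replace(",", " ").split() for ln in lines[start:]]
    arr = np.array([[float(v) for v in r] for r in rows])
    if arr.ndim != 2 or arr.shape[1] > 2:
        raise ValueError(f"{path}: expected 1 or 2 columns, got shape {arr.shape}")
    return arr[:, -1]


def _is_header(line: str) -> bool:
    for tok in line.replace(",", " ").split():
        try:
            float(tok)
        except ValueError:
            return True
    return False


def write_series(path, x: np.ndarray, t: np.ndarray | None = None,
                 header: str = "") -> None:
    """Write a series as one column, or (t, x) as two comma-separated columns."""
    arr = np.asarray(x) if t is None else np.column_stack([t, x])
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
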