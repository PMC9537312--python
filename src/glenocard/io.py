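"""CSV/JSON input and output.

Point lists (rim traces, defect outlines) travel as two-column CSV files
with a mandatory ``x_mm,y_mm`` header.  Reports are JSON with sorted keys
and fixed indentation, so repeated runs with the same inputs are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

POINT_COLUMNS = ("x_mm", "y_mm")


def load_points_csv(path) -> np.ndarray:
    """Read an (n, 2) point array from a ``x_mm,y_mm`` CSV.

    A header-only file yields an empty (0, 2) array (no points).  Malformed
    rows raise :class:`DataError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise DataError(f"{path}: file not found") from None
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file (expected header {','.join(POINT_COLUMNS)})") from None
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: {exc}") from None
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing required column(s) {missing}; header must contain "
            f"{','.join(POINT_COLUMNS)}"
        )
    if df.empty:
        return np.empty((0, 2), dtype=float)
    coerced = df[list(POINT_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise DataError(f"{path}: non-numeric coordinate on line {line}")
    return coerced.to_numpy(dtype=float)


def save_points_csv(path, points: np.ndarray) -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pd.DataFrame(pts, columns=list(POINT_COLUMNS)).to_csv(path, index=False, float_format="%.6f")


def dump_json(obj, path) -> None:
    """Write deterministic JSON (sorted keys, 2-space indent, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
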