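"""Link the indicator grid to geocoded subject addresses.

Each subject carries up to three concurrent addresses (``address_index`` 1-3,
index 1 being the baseline residence used by the demonstration analyses).
Linkage is a point-in-cell lookup on the ~1 km grid — no buffering — under
the package-wide half-open cell convention.  Addresses falling on nodata
cells produce explicit missingness flags, never silent zeros.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .grid import GridSpec
from .indicators import INDICATOR_NAMES, IndicatorGrid

__all__ = ["locate_cell", "link_addresses", "cross_correlation"]

ADDRESS_COLUMNS = ("subject_id", "address_index", "lon", "lat")


def locate_cell(grid: GridSpec, lon: float, lat: float) -> tuple[int, int] | None:
    """Cell (row, col) containing the point, or None if outside the extent.

    Both indices are the floor of the affine inverse, which is the
    south/east boundary rule: a point on a shared vertical edge belongs to
    the cell to its east (the cell whose western edge it lies on), a point
    on a shared horizontal edge to the cell to its south, matching the
    half-open cell extents stated in :mod:`urbansat.grid`.
    """
    col = math.floor((lon - grid.origin_x) / grid.cell_w)
    row = math.floor((grid.origin_y - lat) / grid.cell_h)
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return row, col
    return None


def link_addresses(ind: IndicatorGrid, addresses: pd.DataFrame) -> pd.DataFrame:
    """One output row per address, carrying the 11 indicator values.

    Output columns: subject_id, address_index, lon, lat, cell_row, cell_col,
    the 11 indicators (NaN when missing), one ``<name>_missing`` flag per
    indicator, and ``n_missing``.  Addresses outside the grid extent have
    all indicators missing and cell indices of -1.
    """
    missing_cols = [c for c in ADDRESS_COLUMNS if c not in addresses.columns]
    if missing_cols:
        raise ValueError(f"addresses table lacks columns {missing_cols}")
    dup = addresses.duplicated(subset=["subject_id", "address_index"])
    if dup.any():
        bad = addresses.loc[dup, ["subject_id", "address_index"]].iloc[0]
        raise ValueError(
            "duplicate (subject_id, address_index): "
            f"({bad['subject_id']}, {bad['address_index']})"
        )
    stack = ind.to_array()  # (11, R, C)
    rows = []
    for rec in addresses.itertuples(index=False):
        hit = locate_cell(ind.grid, rec.lon, rec.lat)
        row: dict = {
            "subject_id": rec.subject_id,
            "address_index": int(rec.address_index),
            "lon": rec.lon,
            "lat": rec.lat,
        }
        if hit is None:
            row["cell_row"], row["cell_col"] = -1, -1
            vals = np.full(len(INDICATOR_NAMES), np.nan)
        else:
            row["cell_row"], row["cell_col"] = hit
            vals = stack[:, hit[0], hit[1]]
        for name, v in zip(INDICATOR_NAMES, vals):
            row[name] = v
            row[f"{name}_missing"] = bool(np.isnan(v))
        row["n_missing"] = int(np.isnan(vals).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def cross_correlation(
    table: pd.DataFrame, address_index: int = 1
) -> pd.DataFrame:
    """11x11 Pearson cross-correlation of indicators over linked rows.

    Uses pairwise-complete observations.  The matrix is symmetric with a
    unit diagonal; entries involving a constant (zero-variance) indicator
    are NaN — flagged as undefined rather than silently zero.
    """
    sub = table[table["address_index"] == address_index]
    cols = sub[list(INDICATOR_NAMES)]
    if len(cols.dropna()) < 3:
        raise ValueError("need at least 3 complete rows for cross-correlation")
    corr = cols.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
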