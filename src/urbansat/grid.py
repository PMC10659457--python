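"""Common output grid and exact zonal aggregation of nested fine rasters.

All stages of the pipeline share one coordinate convention, stated here once:
a grid is north-up with its origin at the top-left (north-west) corner; cell
``(r, c)`` covers the half-open extent

    x in [origin_x + c*cell_w, origin_x + (c+1)*cell_w)
    y in (origin_y - (r+1)*cell_h, origin_y - r*cell_h]

so a point on a shared vertical edge belongs to the cell whose *western*
edge it lies on (the cell to the east), and a point on a shared horizontal
edge belongs to the cell whose *northern* edge it lies on (the cell to the
south): the floor of the affine inverse, applied everywhere.

Aggregation from a fine raster into coarse (~1 km) cells requires *exact
integer nesting*: coincident origins, coarse cell sizes that are integer
multiples of the fine cell sizes, and a coarse extent covering the fine
extent.  Arbitrary reprojection/resampling is deliberately out of scope; the
nesting restriction keeps every aggregator exactly testable against a
brute-force per-pixel oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "GridSpec",
    "RasterLayer",
    "NestingReport",
    "GridNestingError",
    "check_nesting",
    "aggregate_fraction",
    "aggregate_sum",
    "aggregate_mean",
    "aggregate_threshold_fraction",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: relative tolerance for "exact" floating comparisons of grid geometry
_GEOM_RTOL = 1e-9


class GridNestingError(ValueError):
    """Raised when a fine grid does not nest exactly inside a coarse grid."""


@dataclass(frozen=True)
class GridSpec:
    """Geo-referenced regular grid (north-up, top-left origin).

    Parameters
    ----------
    origin_x, origin_y
        Coordinates of the top-left (north-west) corner, in CRS units
        (decimal degrees for the default WGS84).
    cell_w, cell_h
        Positive cell sizes in CRS units.
    n_rows, n_cols
        Grid shape; row 0 is the northern edge.
    crs
        Identifier string; grids only interoperate when it matches.
    """

    origin_x: float
    origin_y: float
    cell_w: float
    cell_h: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_w <= 0 or self.cell_h <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_w

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_h

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        return (
            self.origin_x + (col + 0.5) * self.cell_w,
            self.origin_y - (row + 0.5) * self.cell_h,
        )

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.origin_x <= lon < self.x_max
            and self.y_min < lat <= self.origin_y
        )


@dataclass
class RasterLayer:
    """A values matrix bound to a :class:`GridSpec`.

    ``kind`` is ``"categorical"`` (integer class codes) or ``"continuous"``.
    ``nodata`` is the missing-value sentinel: NaN for continuous layers,
    an integer code for categorical ones.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = np.nan
    kind: str = "continuous"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown layer kind {self.kind!r}")

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels that are not nodata."""
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass(frozen=True)
class NestingReport:
    factor_x: int
    factor_y: int


def _is_integer_ratio(coarse_size: float, fine_size: float) -> int | None:
    ratio = coarse_size / fine_size
    factor = round(ratio)
    if factor >= 1 and math.isclose(ratio, factor, rel_tol=_GEOM_RTOL):
        return factor
    return None


def check_nesting(fine: GridSpec, coarse: GridSpec) -> NestingReport:
    """Verify that ``fine`` nests exactly inside ``coarse``.

    Succeeds iff the CRSs match, the coarse cell sizes are exact integer
    multiples of the fine cell sizes, the origins coincide, and the coarse
    extent covers the fine extent.  Returns the integer (x, y) factors.

    Raises
    ------
    GridNestingError
        Naming the violated condition.
    """
    if fine.crs != coarse.crs:
        raise GridNestingError(
            f"CRS mismatch: fine {fine.crs!r} vs coarse {coarse.crs!r}"
        )
    factor_x = _is_integer_ratio(coarse.cell_w, fine.cell_w)
    if factor_x is None:
        raise GridNestingError(
            f"non-integer cell-width ratio {coarse.cell_w}/{fine.cell_w}"
        )
    factor_y = _is_integer_ratio(coarse.cell_h, fine.cell_h)
    if factor_y is None:
        raise GridNestingError(
            f"non-integer cell-height ratio {coarse.cell_h}/{fine.cell_h}"
        )
    tol_x = _GEOM_RTOL * coarse.cell_w
    tol_y = _GEOM_RTOL * coarse.cell_h
    if abs(fine.origin_x - coarse.origin_x) > tol_x or abs(
        fine.origin_y - coarse.origin_y
    ) > tol_y:
        raise GridNestingError(
            "origin offset: fine origin "
            f"({fine.origin_x}, {fine.origin_y}) vs coarse "
            f"({coarse.origin_x}, {coarse.origin_y})"
        )
    if (
        fine.x_max > coarse.x_max + tol_x
        or fine.y_min < coarse.y_min - tol_y
    ):
        raise GridNestingError("coarse extent does not cover fine extent")
    return NestingReport(factor_x=factor_x, factor_y=factor_y)


def _blocked(layer: RasterLayer, coarse: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, valid) reshaped to (Rc, fy, Cc, fx) blocks.

    Fine pixels beyond the fine extent (when coarse covers more area) are
    padded as invalid so they never enter numerators or denominators.
    """
    rep = check_nesting(layer.grid, coarse)
    fy, fx = rep.factor_y, rep.factor_x
    full = np.full(
        (coarse.n_rows * fy, coarse.n_cols * fx), np.nan, dtype=float
    )
    valid = np.zeros_like(full, dtype=bool)
    r, c = layer.grid.shape
    full[:r, :c] = layer.values
    valid[:r, :c] = layer.valid_mask()
    shape = (coarse.n_rows, fy, coarse.n_cols, fx)
    return full.reshape(shape), valid.reshape(shape)


def _finalize(
    num: np.ndarray,
    den: np.ndarray,
    n_valid: np.ndarray,
    block_size: int,
    coverage_min: float,
) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = (den > 0) & (n_valid >= coverage_min * block_size)
    out[ok] = num[ok] / den[ok]
    return out


def aggregate_fraction(
    layer: RasterLayer,
    coarse: GridSpec,
    codes: Iterable[int],
    coverage_min: float = 0.5,
) -> RasterLayer:
    """Per-cell fraction of valid fine pixels whose class code is in ``codes``.

    Cells whose valid-pixel coverage is below ``coverage_min`` are nodata.
    """
    codes = frozenset(int(c) for c in codes)
    if not codes:
        raise ValueError("codes set must not be empty")
    if layer.kind != "categorical":
        raise TypeError("aggregate_fraction requires a categorical layer")
    vals, valid = _blocked(layer, coarse)
    hit = np.isin(vals, sorted(codes)) & valid
    n_valid = valid.sum(axis=(1, 3))
    frac = _finalize(
        hit.sum(axis=(1, 3)).astype(float),
        n_valid.astype(float),
        n_valid,
        vals.shape[1] * vals.shape[3],
        coverage_min,
    )
    return RasterLayer(coarse, frac, nodata=np.nan, kind="continuous", units="fraction")


def aggregate_sum(
    layer: RasterLayer,
    coarse: GridSpec,
    coverage_min: float = 0.0,
) -> RasterLayer:
    """Per-cell sum of valid fine pixel values.

    Nodata pixels are excluded (not treated as zero).  The default
    ``coverage_min`` of 0 preserves conservation: the total over all coarse
    cells equals the total over all valid fine pixels.  An all-nodata cell
    is nodata.
    """
    if layer.kind != "continuous":
        raise TypeError("aggregate_sum requires a continuous layer")
    vals, valid = _blocked(layer, coarse)
    n_valid = valid.sum(axis=(1, 3))
    total = np.where(valid, vals, 0.0).sum(axis=(1, 3))
    out = np.full(total.shape, np.nan)
    block = vals.shape[1] * vals.shape[3]
    ok = (n_valid > 0) & (n_valid >= coverage_min * block)
    out[ok] = total[ok]
    return RasterLayer(coarse, out, nodata=np.nan, kind="continuous", units=layer.units)


def aggregate_mean(
    layer: RasterLayer,
    coarse: GridSpec,
    coverage_min: float = 0.5,
) -> RasterLayer:
    """Per-cell mean of valid fine pixel values (nodata excluded)."""
    if layer.kind != "continuous":
        raise TypeError("aggregate_mean requires a continuous layer")
    vals, valid = _blocked(layer, coarse)
    n_valid = valid.sum(axis=(1, 3))
    total = np.where(valid, vals, 0.0).sum(axis=(1, 3))
    out = _finalize(
        total,
        n_valid.astype(float),
        n_valid,
        vals.shape[1] * vals.shape[3],
        coverage_min,
    )
    return RasterLayer(coarse, out, nodata=np.nan, kind="continuous", units=layer.units)


def aggregate_threshold_fraction(
    layer: RasterLayer,
    coarse: GridSpec,
    threshold: float,
    direction: str = "gt",
    coverage_min: float = 0.5,
) -> RasterLayer:
    """Per-cell fraction of valid fine pixels exceeding ``threshold``.

    ``direction`` is ``"gt"`` (strict, the default — matching "area with
    index over t") or ``"ge"``.
    """
    if layer.kind != "continuous":
        raise TypeError("aggregate_threshold_fraction requires a continuous layer")
    if direction not in ("gt", "ge"):
        raise ValueError(f"direction must be 'gt' or 'ge', got {direction!r}")
    vals, valid = _blocked(layer, coarse)
    with np.errstate(invalid="ignore"):
        hit = (vals > threshold) if direction == "gt" else (vals >= threshold)
    hit &= valid
    n_valid = valid.sum(axis=(1, 3))
    frac = _finalize(
        hit.sum(axis=(1, 3)).astype(float),
        n_valid.astype(float),
        n_valid,
        vals.shape[1] * vals.shape[3],
        coverage_min,
    )
    return RasterLayer(coarse, frac, nodata=np.nan, kind="continuous", units="fraction")


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid), preserving the GridSpec.

def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a square-cell layer as an ESRI ASCII grid (.asc).

    The format stores one cellsize, so ``cell_w`` must equal ``cell_h``.
    Nodata is written as -9999 for continuous layers.
    """
    g = layer.grid
    if not math.isclose(g.cell_w, g.cell_h, rel_tol=_GEOM_RTOL):
        raise ValueError("ASCII grid format requires square cells")
    nodata_out = -9999
    vals = layer.values.astype(float)
    vals = np.where(layer.valid_mask(), vals, nodata_out)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.y_min!r}\n"
        f"cellsize {g.cell_w!r}\n"
        f"NODATA_value {nodata_out}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fmt = "%d" if layer.kind == "categorical" else "%.10g"
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(
    path: str | Path,
    kind: str = "continuous",
    units: str = "",
    crs: str = "EPSG:4326",
) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = hdr["cellsize"]
    grid = GridSpec(
        origin_x=hdr["xllcorner"],
        origin_y=hdr["yllcorner"] + n_rows * cell,
        cell_w=cell,
        cell_h=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs=crs,
    )
    nodata_in = hdr["nodata_value"]
    if kind == "categorical":
        return RasterLayer(
            grid, values.astype(int), nodata=int(nodata_in), kind=kind, units=units
        )
    values = np.where(values == nodata_in, np.nan, values)
    return RasterLayer(grid, values, nodata=np.nan, kind=kind, units=units)
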