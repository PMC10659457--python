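"""Spectral indices and assembly of the 11-layer environmental indicator grid.

The indicator set summarizes, per ~1 km cell: six land-cover class fractions
(built-up, forest, crop, grass, permanent water, seasonal water), the summed
nighttime-light radiance, the summed population count, the area fractions
with NDVI > 0.2 and NDWI > 0.3, and the mean NDBI.

Indices are computed at the *fine* pixel resolution and then aggregated —
"percent area with index over t" semantics — never on pre-aggregated bands.

Normalized-difference formulas (standard remote-sensing definitions):

    NDVI = (NIR - Red) / (NIR + Red)
    NDWI = (Green - NIR) / (Green + NIR)      (McFeeters open-water variant)
    NDBI = (SWIR - NIR) / (SWIR + NIR)

A zero denominator yields nodata.  The NDWI variant is configurable in
spirit: the Gao (NIR - SWIR) soil/vegetation-moisture variant could be
swapped in by changing ``compute_index``; the McFeeters form is the one
consistent with an open-water index thresholded at 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import (
    GridSpec,
    RasterLayer,
    aggregate_fraction,
    aggregate_mean,
    aggregate_sum,
    aggregate_threshold_fraction,
)

__all__ = [
    "INDICATOR_NAMES",
    "BandStack",
    "IndicatorConfig",
    "IndicatorGrid",
    "compute_index",
    "derive_urbansat",
]

#: canonical order of the 11 indicator layers
INDICATOR_NAMES: tuple[str, ...] = (
    "pct_builtup",
    "pct_forest",
    "pct_crop",
    "pct_grass",
    "pct_perm_water",
    "pct_seasonal_water",
    "ntl_sum",
    "population",
    "pct_ndvi_gt",
    "pct_ndwi_gt",
    "ndbi_mean",
)

BAND_NAMES = ("green", "red", "nir", "swir")


@dataclass
class BandStack:
    """Four co-registered surface-reflectance layers on one grid."""

    grid: GridSpec
    green: RasterLayer
    red: RasterLayer
    nir: RasterLayer
    swir: RasterLayer

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            layer: RasterLayer = getattr(self, name)
            if layer.grid != self.grid:
                raise ValueError(f"band {name!r} is not on the stack grid")
            with np.errstate(invalid="ignore"):
                if np.any(layer.values[layer.valid_mask()] < 0):
                    raise ValueError(f"band {name!r} has negative reflectances")


def _default_class_map() -> dict[str, frozenset[int]]:
    return {
        "builtup": frozenset({50}),
        "forest": frozenset(range(111, 117)) | frozenset(range(121, 127)),
        "crop": frozenset({40}),
        "grass": frozenset({30}),
        "permanent_water": frozenset({80}),
        # the source class table lists no seasonal-water code; 90
        # (herbaceous wetland) is the configurable default
        "seasonal_water": frozenset({90}),
    }


@dataclass
class IndicatorConfig:
    """Class codes and thresholds driving indicator derivation."""

    class_map: Mapping[str, frozenset[int]] = field(default_factory=_default_class_map)
    ndvi_threshold: float = 0.2
    ndwi_threshold: float = 0.3
    ndwi_variant: str = "green_nir"
    coverage_min: float = 0.5

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, codes in self.class_map.items():
            codes = frozenset(codes)
            if seen & codes:
                raise ValueError(
                    f"class set {name!r} overlaps another class set: "
                    f"{sorted(seen & codes)}"
                )
            seen |= codes
        for t in (self.ndvi_threshold, self.ndwi_threshold):
            if not -1.0 < t < 1.0:
                raise ValueError(f"index threshold {t} outside (-1, 1)")

    @property
    def all_codes(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for codes in self.class_map.values():
            out |= codes
        return out


@dataclass
class IndicatorGrid:
    """The 11 named indicator layers on a shared ~1 km grid, fixed order."""

    grid: GridSpec
    layers: dict[str, RasterLayer]

    def __post_init__(self) -> None:
        if tuple(self.layers) != INDICATOR_NAMES:
            raise ValueError(
                "layers must be exactly the 11 indicators in canonical "
                f"order; got {tuple(self.layers)}"
            )
        for name, layer in self.layers.items():
            if layer.grid != self.grid:
                raise ValueError(f"layer {name!r} not on the indicator grid")

    def to_array(self) -> np.ndarray:
        """Stacked (11, n_rows, n_cols) array in canonical layer order."""
        return np.stack([self.layers[n].values for n in INDICATOR_NAMES])


def compute_index(bands: BandStack, which: str) -> RasterLayer:
    """Compute NDVI, NDWI or NDBI at fine resolution; zero denominator → nodata."""
    pairs = {
        "ndvi": (bands.nir, bands.red),
        "ndwi": (bands.green, bands.nir),
        "ndbi": (bands.swir, bands.nir),
    }
    if which not in pairs:
        raise ValueError(f"unknown index {which!r}; expected ndvi/ndwi/ndbi")
    a, b = pairs[which]
    num = a.values - b.values
    den = a.values + b.values
    valid = a.valid_mask() & b.valid_mask() & (den != 0)
    out = np.full(den.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[valid] = num[valid] / den[valid]
    return RasterLayer(bands.grid, out, nodata=np.nan, kind="continuous", units="index")


def derive_urbansat(
    lulc: RasterLayer,
    ntl: RasterLayer,
    pop: RasterLayer,
    bands: BandStack,
    coarse: GridSpec,
    cfg: IndicatorConfig | None = None,
) -> IndicatorGrid:
    """Assemble the 11-layer indicator grid from fine-resolution inputs.

    Class fractions come from zonal fractions of the categorical land-cover
    raster; radiance and population are zonal sums (conserving totals);
    NDVI/NDWI area fractions use strict thresholds at fine resolution;
    NDBI is the zonal mean over valid pixels.
    """
    cfg = cfg or IndicatorConfig()
    cm = cfg.coverage_min
    fraction_order = (
        "builtup",
        "forest",
        "crop",
        "grass",
        "permanent_water",
        "seasonal_water",
    )
    layers: dict[str, RasterLayer] = {}
    for ind_name, class_name in zip(INDICATOR_NAMES[:6], fraction_order):
        layers[ind_name] = aggregate_fraction(
            lulc, coarse, cfg.class_map[class_name], coverage_min=cm
        )
    layers["ntl_sum"] = aggregate_sum(ntl, coarse)
    layers["population"] = aggregate_sum(pop, coarse)
    ndvi = compute_index(bands, "ndvi")
    ndwi = compute_index(bands, "ndwi")
    ndbi = compute_index(bands, "ndbi")
    layers["pct_ndvi_gt"] = aggregate_threshold_fraction(
        ndvi, coarse, cfg.ndvi_threshold, direction="gt", coverage_min=cm
    )
    layers["pct_ndwi_gt"] = aggregate_threshold_fraction(
        ndwi, coarse, cfg.ndwi_threshold, direction="gt", coverage_min=cm
    )
    layers["ndbi_mean"] = aggregate_mean(ndbi, coarse, coverage_min=cm)
    return IndicatorGrid(grid=coarse, layers=layers)
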