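"""Derive the 11 environmental indicators on the ~1 km grid.

Reads the fine rasters written by 01, aggregates them onto the exactly
nesting coarse grid (land-cover fractions, radiance and population sums,
NDVI/NDWI area fractions, mean NDBI) and writes one ASCII grid per
indicator layer.
"""

from pathlib import Path

import numpy as np

from urbansat import BandStack, derive_urbansat
from urbansat.grid import read_ascii_grid, write_ascii_grid
from urbansat.indicators import INDICATOR_NAMES
from urbansat.synth import default_coarse_grid

WORLD = Path(__file__).resolve().parents[1] / "results" / "world"
OUT = Path(__file__).resolve().parents[1] / "results" / "indicators"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lulc = read_ascii_grid(WORLD / "lulc.asc", kind="categorical")
    ntl = read_ascii_grid(WORLD / "ntl.asc", units="nW/cm^2/sr")
    pop = read_ascii_grid(WORLD / "pop.asc", units="persons")
    bands = BandStack(
        lulc.grid,
        *(read_ascii_grid(WORLD / f"bands_{b}.asc", units="reflectance")
          for b in ("green", "red", "nir", "swir")),
    )
    coarse = default_coarse_grid(lulc.grid, factor=10)
    ind = derive_urbansat(lulc, ntl, pop, bands, coarse)
    for name in INDICATOR_NAMES:
        write_ascii_grid(ind.layers[name], OUT / f"{name}.asc")
    print(f"derived {len(ind.layers)} indicator layers on a "
          f"{coarse.n_rows}x{coarse.n_cols} ~1 km grid -> {OUT}")
    for name in INDICATOR_NAMES:
        v = ind.layers[name].values
        print(f"  {name:<20} mean {np.nanmean(v):10.4f}")


if __name__ == "__main__":
    main()
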