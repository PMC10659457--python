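"""Simulate one synthetic study world and write its raw inputs to disk.

Generates the default world (seed 42, 1000 subjects across 21 sites on a
240x240 fine grid) with the planted ground truth — an NDBI effect on the
cognitive score and a nighttime-light coupling on DMN connectivity — and
writes the categorical land-cover raster, the nighttime-light and
population rasters, the four reflectance bands (ESRI ASCII grids), the
subject and address tables, and the ground-truth parameters.  Everything
downstream (02-05) recomputes from these files.
"""

from pathlib import Path

from urbansat import simulate_study
from urbansat.grid import write_ascii_grid

OUT = Path(__file__).resolve().parents[1] / "results" / "world"
SEED = 42
N_SUBJECTS = 1000
N_SITES = 21


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(n_subjects=N_SUBJECTS, n_sites=N_SITES, seed=SEED)

    write_ascii_grid(study.lulc, OUT / "lulc.asc")
    write_ascii_grid(study.ntl, OUT / "ntl.asc")
    write_ascii_grid(study.pop, OUT / "pop.asc")
    for name in ("green", "red", "nir", "swir"):
        write_ascii_grid(getattr(study.bands, name), OUT / f"bands_{name}.asc")

    study.subjects.to_csv(OUT / "subjects.csv", index=False)
    study.addresses.to_csv(OUT / "addresses.csv", index=False)
    (OUT / "truth.json").write_text(study.truth.to_json() + "\n")

    grid = study.fine_grid
    print(f"world written to {OUT}")
    print(f"  {N_SUBJECTS} subjects, {len(study.addresses)} addresses, "
          f"{N_SITES} sites, grid {grid.n_rows}x{grid.n_cols}")
    print(f"  population total {study.pop.values.sum():.0f} "
          f"(requested {study.truth.total_population:.0f})")


if __name__ == "__main__":
    main()
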