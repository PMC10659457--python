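"""Synthetic worlds with planted ground truth for every pipeline stage.

This module generates everything the pipeline consumes — land-cover,
nighttime-light, population and reflectance rasters; a clustered cohort
(sites, families-in-sites) with geocoded addresses, SES covariates and
behavioral/cognitive outcomes; and per-subject ICN time courses — from a
single :class:`SimulationTruth` of known parameters, so that downstream
aggregation, linkage, connectome and mixed-model stages can be tested for
exact recovery with no external data.

What the generator emulates, and how:

* **Land cover** — spatially autocorrelated class patches via block
  partition sampling: the fine grid is tiled into fixed-size super-blocks,
  each assigned a single class code drawn from the configured mixture.
  Empirical class frequencies converge to the mixture as the block count
  grows, and ~1 km cells genuinely differ in composition.
* **Nighttime lights / population** — radiance is gamma-distributed around
  a class-dependent mean (urban ≫ rural); population mass is allocated by
  class-dependent weights with multiplicative heterogeneity and normalized
  so the raster sums exactly to the requested total (conservation).
* **Reflectance bands** — class-conditional band means plus Gaussian noise,
  clipped to [0, 1].  The default means place vegetation classes above the
  NDVI 0.2 threshold, open water above the NDWI 0.3 threshold, and built-up
  at positive NDBI.
* **Cohort** — subjects are assigned to K sites (default 21) with families
  of 1-3 nested in sites; addresses (1-3 per subject) scatter around site
  centers inside the grid extent.  Outcomes follow the same linear mixed
  model the analysis fits: planted fixed effects on *z-scored* indicator
  exposures, optional direct SES effects, Gaussian site and family random
  intercepts, Gaussian residual.  SES ordinals are coupled to built-up
  exposure with correlation ``ses_rho`` (negative direction: denser
  surroundings, lower SES), reproducing the exposure-SES multicollinearity
  that motivates fitting model sets with and without SES.
* **ICN time courses** — a single shared latent factor with node loadings
  that are larger for DMN nodes and increase with
  ``beta_exposure_dmn x exposure``, plus unit white noise.  Raising the
  exposure therefore raises within-DMN and DMN-to-rest correlations and,
  monotonically in expectation, the DMN clustering coefficient.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import GridSpec, RasterLayer
from .indicators import (
    BAND_NAMES,
    INDICATOR_NAMES,
    BandStack,
    IndicatorConfig,
    IndicatorGrid,
    derive_urbansat,
)
from .linkage import link_addresses
from .connectome import DEFAULT_DMN_INDICES, DEFAULT_N_ICNS, dmn_clustering_batch

__all__ = [
    "SimulationTruth",
    "default_truth",
    "default_fine_grid",
    "default_coarse_grid",
    "simulate_lulc",
    "simulate_ntl_pop",
    "simulate_bands",
    "simulate_cohort",
    "simulate_icn_timeseries",
    "SimulatedStudy",
    "simulate_study",
]

OUTCOMES = ("cbcl_total", "cog_total")
SES_VARS = ("household_income", "parent_education")

#: default land-cover mixture over Copernicus-style class codes
_DEFAULT_MIXTURE = {
    111: 0.18,  # closed forest
    121: 0.07,  # open forest
    30: 0.15,   # herbaceous vegetation (grass)
    40: 0.20,   # cropland
    50: 0.25,   # urban / built up
    80: 0.05,   # permanent inland water
    90: 0.10,   # seasonal water (wetland-like)
}


def _default_band_means() -> dict[tuple[int, str], float]:
    """Class-conditional reflectance means (fractions).

    Chosen so vegetation classes sit well above NDVI 0.2, open water above
    NDWI 0.3, and built-up at NDVI < 0.2 with NDBI > 0.
    """
    per_class = {
        # green, red, nir, swir
        30: (0.07, 0.08, 0.33, 0.20),   # grass: NDVI 0.61
        40: (0.07, 0.07, 0.36, 0.20),   # crop: NDVI 0.67
        50: (0.12, 0.14, 0.17, 0.27),   # urban: NDVI 0.10, NDBI +0.23
        80: (0.06, 0.05, 0.02, 0.01),   # water: NDWI 0.5, NDVI -0.43
        90: (0.08, 0.07, 0.15, 0.08),   # wetland: mixed signal
    }
    forest = (0.05, 0.04, 0.45, 0.18)   # NDVI 0.84, NDBI -0.43
    for code in (*range(111, 117), *range(121, 127)):
        per_class[code] = forest
    return {
        (code, band): val
        for code, vals in per_class.items()
        for band, val in zip(BAND_NAMES, vals)
    }


def _default_betas() -> dict[tuple[str, str], float]:
    """Planted indicator→outcome fixed effects, outcome units per indicator SD.

    The defaults plant the two headline directions the association suite
    must recover: denser built environment (NDBI) lowering cognitive score,
    with nighttime lights acting on the brain outcome through
    ``beta_exposure_dmn`` (see :func:`simulate_icn_timeseries`).
    """
    return {("ndbi_mean", "cog_total"): -0.15}


@dataclass
class SimulationTruth:
    """All ground-truth parameters of a synthetic study world."""

    class_mixture: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    ntl_urban_mean: float = 40.0      # nW/cm^2/sr
    ntl_rural_mean: float = 1.0
    total_population: float = 250_000.0
    band_means: dict[tuple[int, str], float] = field(
        default_factory=_default_band_means
    )
    band_noise_sd: float = 0.02
    beta_indicator_outcome: dict[tuple[str, str], float] = field(
        default_factory=_default_betas
    )
    beta_ses_outcome: dict[tuple[str, str], float] = field(default_factory=dict)
    beta_exposure_dmn: float = 0.06   # DMN factor-loading units per exposure SD
    ses_rho: float = 0.4
    site_sd: float = 0.3
    family_sd: float = 0.5
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.class_mixture.values()), dtype=float)
        if np.any(probs < 0):
            raise ValueError("class_mixture probabilities must be nonnegative")
        if not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ValueError(
                f"class_mixture probabilities sum to {probs.sum()}, not 1"
            )
        for name in ("site_sd", "family_sd", "residual_sd", "band_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_population < 0:
            raise ValueError("total_population must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["class_mixture"] = {str(k): v for k, v in d["class_mixture"].items()}
        d["band_means"] = {f"{c}:{b}": v for (c, b), v in d["band_means"].items()}
        d["beta_indicator_outcome"] = {
            f"{i}:{o}": v for (i, o), v in d["beta_indicator_outcome"].items()
        }
        d["beta_ses_outcome"] = {
            f"{s}:{o}": v for (s, o), v in d["beta_ses_outcome"].items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


def default_truth(**overrides) -> SimulationTruth:
    return SimulationTruth(**overrides)


def default_fine_grid(n: int = 240, cell: float = 0.001) -> GridSpec:
    """~100 m-equivalent fine grid (0.001 deg cells) over a small region."""
    return GridSpec(
        origin_x=-100.0, origin_y=40.0, cell_w=cell, cell_h=cell,
        n_rows=n, n_cols=n,
    )


def default_coarse_grid(fine: GridSpec, factor: int = 10) -> GridSpec:
    """~1 km coarse grid exactly nesting the fine grid (integer factor)."""
    if fine.n_rows % factor or fine.n_cols % factor:
        raise ValueError("fine grid shape must be divisible by the factor")
    return GridSpec(
        origin_x=fine.origin_x,
        origin_y=fine.origin_y,
        cell_w=fine.cell_w * factor,
        cell_h=fine.cell_h * factor,
        n_rows=fine.n_rows // factor,
        n_cols=fine.n_cols // factor,
        crs=fine.crs,
    )


def _rng(truth: SimulationTruth, rng: np.random.Generator | None, salt: int):
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([truth.seed, salt]))


def simulate_lulc(
    grid: GridSpec,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    block_size: int = 8,
) -> RasterLayer:
    """Blocky categorical land-cover raster following the truth mixture.

    The grid is tiled with ``block_size`` x ``block_size`` super-blocks;
    each block gets one class code drawn from the mixture, giving spatially
    autocorrelated patches rather than i.i.d. pixel noise.
    """
    if grid.n_rows < 10 or grid.n_cols < 10:
        raise ValueError("fine grid must be at least 10x10 pixels")
    valid = IndicatorConfig().all_codes
    bad = set(truth.class_mixture) - set(valid)
    if bad:
        raise ValueError(f"mixture contains unconfigured class codes {sorted(bad)}")
    rng = _rng(truth, rng, 1)
    codes = np.array(sorted(truth.class_mixture))
    probs = np.array([truth.class_mixture[c] for c in codes])
    probs = probs / probs.sum()
    n_br = -(-grid.n_rows // block_size)
    n_bc = -(-grid.n_cols // block_size)
    blocks = rng.choice(codes, size=(n_br, n_bc), p=probs)
    full = np.repeat(np.repeat(blocks, block_size, axis=0), block_size, axis=1)
    values = full[: grid.n_rows, : grid.n_cols]
    return RasterLayer(grid, values, nodata=-1, kind="categorical", units="class")


#: class-dependent population-allocation weights (people gravitate to
#: built-up, then cultivated land; open water carries almost none)
_POP_WEIGHTS = {50: 20.0, 40: 2.0, 30: 2.0, 80: 0.05, 90: 0.2}
_POP_WEIGHT_DEFAULT = 0.5


def simulate_ntl_pop(
    grid: GridSpec,
    lulc: RasterLayer,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> tuple[RasterLayer, RasterLayer]:
    """Radiance and population rasters conditioned on land cover.

    Radiance is gamma-noise around the urban/rural mean (urban = built-up
    code 50); population is allocated by class weights with gamma
    heterogeneity and normalized to sum exactly to ``total_population``.
    """
    if lulc.grid != grid:
        raise ValueError("lulc raster is not on the requested grid")
    rng = _rng(truth, rng, 2)
    urban = lulc.values == 50
    means = np.where(urban, truth.ntl_urban_mean, truth.ntl_rural_mean).astype(float)
    # gamma(shape k, scale mean/k): mean preserved, CV 1/sqrt(k); zero mean -> zero
    k = 3.0
    radiance = rng.gamma(k, np.maximum(means, 0.0) / k)
    ntl = RasterLayer(grid, radiance, kind="continuous", units="nW/cm^2/sr")

    w = np.full(grid.shape, _POP_WEIGHT_DEFAULT)
    for code, weight in _POP_WEIGHTS.items():
        w[lulc.values == code] = weight
    w = w * rng.gamma(2.0, 0.5, size=grid.shape)
    total_w = w.sum()
    if total_w == 0:
        pop_vals = np.zeros(grid.shape)
    else:
        pop_vals = truth.total_population * w / total_w
    pop = RasterLayer(grid, pop_vals, kind="continuous", units="persons")
    return ntl, pop


def simulate_bands(
    grid: GridSpec,
    lulc: RasterLayer,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> BandStack:
    """Class-conditional reflectance bands with Gaussian noise, in [0, 1]."""
    if lulc.grid != grid:
        raise ValueError("lulc raster is not on the requested grid")
    rng = _rng(truth, rng, 3)
    present = np.unique(lulc.values[lulc.valid_mask()])
    layers = {}
    for band in BAND_NAMES:
        mean = np.zeros(grid.shape)
        for code in present:
            key = (int(code), band)
            if key not in truth.band_means:
                raise ValueError(
                    f"band_means missing class {int(code)} for band {band!r}"
                )
            mean[lulc.values == code] = truth.band_means[key]
        vals = mean + rng.normal(0.0, truth.band_noise_sd, size=grid.shape)
        vals = np.clip(vals, 0.0, 1.0)
        layers[band] = RasterLayer(grid, vals, kind="continuous", units="reflectance")
    return BandStack(grid=grid, **layers)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def simulate_cohort(
    n_subjects: int,
    n_sites: int,
    truth: SimulationTruth,
    exposure: pd.DataFrame | None = None,
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
    addr_jitter: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clustered cohort with addresses, SES, and mixed-model outcomes.

    Parameters
    ----------
    exposure
        Optional (n_subjects x indicators) table of raw indicator exposures
        used to plant fixed effects and couple SES; ``None`` means a null
        world (all exposures zero).  Columns are z-scored internally, so
        ``truth.beta_indicator_outcome`` is in outcome units per exposure SD.
    grid
        Extent within which addresses are placed (the fine grid); defaults
        to :func:`default_fine_grid`.
    addr_jitter
        SD of the address scatter around site centers, as a fraction of the
        grid extent.

    Returns
    -------
    (subjects, addresses)
        ``subjects``: one row per subject with site_id, family_id, age
        (months), sex, ordinal SES, cbcl_total and cog_total.
        ``addresses``: 1-3 rows per subject (subject_id, address_index,
        lon, lat), all inside the grid extent.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if n_subjects < n_sites:
        raise ValueError("need n_subjects >= n_sites")
    rng = _rng(truth, rng, 4)
    grid = grid or default_fine_grid()

    site_ids = np.array([f"site{k:02d}" for k in range(n_sites)])
    site_of = np.sort(rng.integers(0, n_sites, size=n_subjects))

    # families of size 1-3 nested in sites
    family_of = np.empty(n_subjects, dtype=object)
    fam_counter = 0
    for k in range(n_sites):
        members = np.flatnonzero(site_of == k)
        i = 0
        while i < len(members):
            size = int(rng.integers(1, 4))
            fam = f"fam{fam_counter:05d}"
            for j in members[i : i + size]:
                family_of[j] = fam
            fam_counter += 1
            i += size

    age = rng.integers(107, 133, size=n_subjects)
    sex = rng.choice(["F", "M"], size=n_subjects)

    if exposure is None:
        z = pd.DataFrame(
            np.zeros((n_subjects, len(INDICATOR_NAMES))), columns=INDICATOR_NAMES
        )
    else:
        if len(exposure) != n_subjects:
            raise ValueError("exposure table length must equal n_subjects")
        z = exposure.reset_index(drop=True).apply(
            lambda col: pd.Series(_standardize(col.to_numpy())), axis=0
        )
        z = z.fillna(0.0)

    # SES ordinals coupled (negatively) to built-up exposure
    rho = truth.ses_rho
    u = z["pct_builtup"].to_numpy() if "pct_builtup" in z else np.zeros(n_subjects)
    lat_inc = -rho * u + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n_subjects)
    lat_edu = -rho * u + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n_subjects)
    from scipy.stats import norm

    income = np.clip(np.digitize(norm.cdf(lat_inc), np.linspace(0, 1, 11)[1:-1]) + 1, 1, 10)
    education = np.clip(np.digitize(norm.cdf(lat_edu), np.linspace(0, 1, 6)[1:-1]) + 1, 1, 5)

    site_b = rng.normal(0.0, truth.site_sd, size=n_sites)[site_of]
    fam_codes, fam_idx = np.unique(family_of, return_inverse=True)
    fam_b = rng.normal(0.0, truth.family_sd, size=len(fam_codes))[fam_idx]

    intercepts = {"cbcl_total": 18.0, "cog_total": 85.0}
    ses_z = {
        "household_income": _standardize(income),
        "parent_education": _standardize(education),
    }
    outcomes = {}
    for outcome in OUTCOMES:
        y = np.full(n_subjects, intercepts[outcome])
        for (ind, out_name), beta in truth.beta_indicator_outcome.items():
            if out_name == outcome and ind in z:
                y = y + beta * z[ind].to_numpy()
        for (ses_var, out_name), beta in truth.beta_ses_outcome.items():
            if out_name == outcome:
                y = y + beta * ses_z[ses_var]
        y = y + site_b + fam_b + rng.normal(0.0, truth.residual_sd, size=n_subjects)
        if outcome == "cbcl_total":
            y = np.maximum(np.round(y), 0.0)
        outcomes[outcome] = y

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub{i:05d}" for i in range(n_subjects)],
            "site_id": site_ids[site_of],
            "family_id": family_of,
            "age": age,
            "sex": sex,
            "household_income": income,
            "parent_education": education,
            "cbcl_total": outcomes["cbcl_total"],
            "cog_total": outcomes["cog_total"],
        }
    )

    # addresses: 1-3 per subject, scattered around site centers, clipped
    # inside the (half-open) grid extent
    margin_x = 0.1 * (grid.x_max - grid.origin_x)
    margin_y = 0.1 * (grid.origin_y - grid.y_min)
    cx = rng.uniform(grid.origin_x + margin_x, grid.x_max - margin_x, size=n_sites)
    cy = rng.uniform(grid.y_min + margin_y, grid.origin_y - margin_y, size=n_sites)
    jit_x = addr_jitter * (grid.x_max - grid.origin_x)
    jit_y = addr_jitter * (grid.origin_y - grid.y_min)
    n_addr = rng.choice([1, 2, 3], size=n_subjects, p=[0.6, 0.3, 0.1])
    eps = 1e-9
    rows = []
    for i in range(n_subjects):
        k = site_of[i]
        for a in range(1, int(n_addr[i]) + 1):
            lon = np.clip(
                cx[k] + rng.normal(0, jit_x),
                grid.origin_x,
                grid.x_max - eps * grid.cell_w,
            )
            lat = np.clip(
                cy[k] + rng.normal(0, jit_y),
                grid.y_min + eps * grid.cell_h,
                grid.origin_y,
            )
            rows.append(
                {
                    "subject_id": subjects.at[i, "subject_id"],
                    "address_index": a,
                    "lon": float(lon),
                    "lat": float(lat),
                }
            )
    addresses = pd.DataFrame(rows)
    return subjects, addresses


def simulate_icn_timeseries(
    n_subjects: int,
    exposure: np.ndarray,
    truth: SimulationTruth,
    n_icns: int = DEFAULT_N_ICNS,
    dmn_indices: tuple[int, ...] = DEFAULT_DMN_INDICES,
    T: int = 150,
    rng: np.random.Generator | None = None,
    base_dmn_loading: float = 0.6,
    rest_loading: float = 0.25,
    rest_coupling: float = 0.4,
    noise_sd: float = 1.0,
    shared_factor: bool = True,
) -> np.ndarray:
    """Latent-factor ICN time courses with an exposure-scaled DMN coupling.

    Node ``j`` of subject ``i`` is ``a_ij * f_i(t) + noise`` with a single
    shared factor ``f_i``.  DMN loadings are
    ``base_dmn_loading + beta_exposure_dmn * exposure_i`` and the remaining
    nodes load ``rest_loading + rest_coupling * beta_exposure_dmn *
    exposure_i`` (floored at 0), so higher exposure strengthens within-DMN
    and DMN-to-rest connectivity and hence the DMN clustering coefficient.
    With ``shared_factor=False`` (or zero loadings) the series are pure
    white noise and the expected FNC off-diagonals are 0.

    Returns an (n_subjects, n_icns, T) array.
    """
    if T < 3:
        raise ValueError("need T >= 3 time points")
    dmn = tuple(int(i) for i in dmn_indices)
    if any(not 0 <= i < n_icns for i in dmn) or len(set(dmn)) != len(dmn):
        raise ValueError("dmn_indices must be distinct nodes within range")
    exposure = np.asarray(exposure, dtype=float)
    if exposure.shape != (n_subjects,):
        raise ValueError("exposure must be one value per subject")
    rng = _rng(truth, rng, 5)
    noise = rng.normal(0.0, noise_sd, size=(n_subjects, n_icns, T))
    if not shared_factor:
        return noise
    f = rng.normal(size=(n_subjects, 1, T))
    delta = truth.beta_exposure_dmn * exposure
    loadings = np.empty((n_subjects, n_icns))
    is_dmn = np.zeros(n_icns, dtype=bool)
    is_dmn[list(dmn)] = True
    loadings[:, is_dmn] = np.maximum(base_dmn_loading + delta[:, None], 0.0)
    loadings[:, ~is_dmn] = np.maximum(
        rest_loading + rest_coupling * delta[:, None], 0.0
    )
    return loadings[:, :, None] * f + noise


@dataclass
class SimulatedStudy:
    """Bundle of all artifacts of one synthetic study world."""

    truth: SimulationTruth
    fine_grid: GridSpec
    coarse_grid: GridSpec
    lulc: RasterLayer
    ntl: RasterLayer
    pop: RasterLayer
    bands: BandStack
    indicator_grid: IndicatorGrid
    subjects: pd.DataFrame
    addresses: pd.DataFrame
    linked: pd.DataFrame
    icn: np.ndarray
    dmn_metrics: pd.DataFrame


def simulate_study(
    truth: SimulationTruth | None = None,
    n_subjects: int = 1000,
    n_sites: int = 21,
    fine_grid: GridSpec | None = None,
    factor: int = 10,
    T: int = 150,
    dmn_exposure_indicator: str = "ntl_sum",
    seed: int | None = None,
    cfg: IndicatorConfig | None = None,
) -> SimulatedStudy:
    """Run the full generative pipeline for one synthetic study world.

    Rasters are simulated on the fine grid, indicators derived on the
    exactly nesting coarse grid, addresses linked (baseline address 1
    defines each subject's exposure), outcomes generated from the planted
    mixed model, and ICN time courses generated with the DMN coupling
    driven by the z-scored ``dmn_exposure_indicator`` (nighttime lights by
    default).
    """
    truth = truth or default_truth()
    if seed is not None:
        truth = SimulationTruth(**{**asdict_truth(truth), "seed": seed})
    fine_grid = fine_grid or default_fine_grid()
    coarse = default_coarse_grid(fine_grid, factor)

    lulc = simulate_lulc(fine_grid, truth)
    ntl, pop = simulate_ntl_pop(fine_grid, lulc, truth)
    bands = simulate_bands(fine_grid, lulc, truth)
    ind = derive_urbansat(lulc, ntl, pop, bands, coarse, cfg)

    # two passes: place the cohort, read exposures at the baseline address,
    # then regenerate outcomes from the planted model with those exposures
    rng_struct = _rng(truth, None, 4)
    subjects0, addresses = simulate_cohort(
        n_subjects, n_sites, truth, exposure=None, grid=fine_grid, rng=rng_struct
    )
    linked = link_addresses(ind, addresses)
    base = linked[linked["address_index"] == 1].set_index("subject_id")
    exposure = base.loc[subjects0["subject_id"], list(INDICATOR_NAMES)].reset_index(
        drop=True
    )
    rng_outcome = _rng(truth, None, 4)
    subjects, addresses2 = simulate_cohort(
        n_subjects, n_sites, truth, exposure=exposure, grid=fine_grid, rng=rng_outcome
    )
    assert addresses2.equals(addresses)

    expo_scalar = _standardize(exposure[dmn_exposure_indicator].to_numpy())
    icn = simulate_icn_timeseries(n_subjects, expo_scalar, truth, T=T)
    dmn = dmn_clustering_batch(icn)
    dmn_metrics = pd.DataFrame(
        {"subject_id": subjects["subject_id"], "dmn_clustering": dmn}
    )
    return SimulatedStudy(
        truth=truth,
        fine_grid=fine_grid,
        coarse_grid=coarse,
        lulc=lulc,
        ntl=ntl,
        pop=pop,
        bands=bands,
        indicator_grid=ind,
        subjects=subjects,
        addresses=addresses,
        linked=linked,
        icn=icn,
        dmn_metrics=dmn_metrics,
    )


def asdict_truth(truth: SimulationTruth) -> dict:
    """Shallow field dict of a truth object (tuple-keyed maps preserved)."""
    return {
        "class_mixture": dict(truth.class_mixture),
        "ntl_urban_mean": truth.ntl_urban_mean,
        "ntl_rural_mean": truth.ntl_rural_mean,
        "total_population": truth.total_population,
        "band_means": dict(truth.band_means),
        "band_noise_sd": truth.band_noise_sd,
        "beta_indicator_outcome": dict(truth.beta_indicator_outcome),
        "beta_ses_outcome": dict(truth.beta_ses_outcome),
        "beta_exposure_dmn": truth.beta_exposure_dmn,
        "ses_rho": truth.ses_rho,
        "site_sd": truth.site_sd,
        "family_sd": truth.family_sd,
        "residual_sd": truth.residual_sd,
        "seed": truth.seed,
    }
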