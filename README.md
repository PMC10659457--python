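# urbansat

Satellite-derived environmental exposure indicators for multi-site cohort
studies — from raw rasters to per-subject exposures, a brain-network
summary metric, and mixed-model association screens, with a fully synthetic
data generator so the entire pipeline runs and is testable with no external
data.

## The problem

Environmental epidemiology increasingly links remote-sensing products to
cohort outcomes: how do urbanization, greenness, nighttime illumination or
population density around a child's home relate to behavior, cognition and
brain development?  Doing this credibly requires a reproducible chain:

1. **Harmonize** multi-source rasters — categorical land cover (Copernicus
   class codes), nighttime-light radiance (~500 m), population counts
   (~100 m), multispectral reflectance — onto one ~1 km grid with identical
   extent and pixel locations (here: exact integer nesting, so every zonal
   statistic is exactly testable).
2. **Derive** 11 indicators per cell: six land-cover class fractions
   (built-up, forest, crop, grass, permanent water, seasonal water), summed
   night-light radiance, summed population, the area fractions with
   NDVI > 0.2 and NDWI > 0.3, and the mean NDBI, where

   NDVI = (NIR−Red)/(NIR+Red), NDWI = (Green−NIR)/(Green+NIR),
   NDBI = (SWIR−NIR)/(SWIR+NIR).

3. **Link** each subject's up-to-three geocoded addresses to their grid
   cell (point-in-cell, explicit missingness — never silent zeros).
4. **Summarize brain function**: from 53 intrinsic-connectivity-network
   (ICN) time courses per subject, compute functional network connectivity
   (FNC, pairwise Pearson correlations) and the average Onnela weighted
   clustering coefficient over the 7 default-mode-network (DMN) nodes,

   C_i = Σ_{j≠h} (w̃_ij w̃_jh w̃_ih)^{1/3} / (k_i (k_i − 1)),

   with weights |r| normalized by the maximum off-diagonal weight.
5. **Associate**: per indicator and outcome (CBCL total problem score,
   cognitive total score, DMN clustering), fit linear mixed models with
   site and family-in-site random intercepts, with and without SES
   covariates (household income, parental education), labelling results by
   a Bonferroni threshold (0.05/11 ≈ 4.5e-3) with a "trending" band up to
   0.01.

Because exposure and SES are strongly collinear in real cohorts, the
package also ships the SES screen and the dual model-set design, and its
synthetic generator plants exactly this confounding so the design can be
exercised.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a synthetic
world (seed 42, 1000 subjects, 21 sites, 240×240 fine grid aggregated to a
24×24 ~1 km grid) and write their tables under `results/`:

```bash
python analysis/01_simulate_world.py     # rasters + cohort + ground truth
python analysis/02_derive_indicators.py  # the 11 ~1 km indicator layers
python analysis/03_link_exposures.py     # per-address exposures + 11x11 correlation
python analysis/04_connectome_metrics.py # FNC + DMN clustering per subject
python analysis/05_associations.py       # SES screen + mixed-model suites
```

Representative printed output:

```
linked 1533 addresses; 0 rows with missing indicators
  corr(pct_builtup, ntl_sum) = +0.993
  corr(pct_forest, ndbi_mean) = -0.519
DMN clustering for 1000 subjects (53 ICN nodes, 7 DMN nodes, T=150)
  mean 0.2720, sd 0.0312
SES screen: strongest correlation household_income x pct_builtup: r=-0.411
...
ndbi_mean   cog_total:       1.85e-05  1.69%(-)      [with SES]
ntl_sum     dmn_clustering:  1.97e-101 29.17%(+)     [with SES]
```

Reading this: urbanization indicators co-vary strongly and oppose
forest/NDVI; income is lower where built-up density is higher (the planted
confounding); and the two planted ground-truth effects — a negative NDBI
effect on cognitive score and a positive nighttime-light coupling on DMN
connectivity — are flagged significant by the with-SES models, with the
expected attenuation relative to the no-SES models.

A library-level one-liner produces the same world in memory:

```python
from urbansat import simulate_study, run_association_suite
s = simulate_study(n_subjects=1000, seed=42)
report = run_association_suite(s.linked, s.subjects, s.dmn_metrics)
```

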