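# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it.

## Grid model and zonal aggregation

A `GridSpec` is a north-up regular grid identified by its top-left corner,
positive cell sizes, shape and a CRS string.  Cell (r, c) covers the
half-open extent `[x0 + c·w, x0 + (c+1)·w) × (y0 − (r+1)·h, y0 − r·h]`;
points on shared edges therefore belong to the cell to the south/east, and
point lookup is the floor of the affine inverse.  This one convention is
used by aggregation and address linkage alike.

Aggregation requires *exact integer nesting*: coincident origins, integer
cell-size ratios, and a coarse extent covering the fine extent.  Arbitrary
reprojection/resampling is deliberately out of scope — the nesting
restriction makes every aggregator exactly equal to a brute-force per-pixel
double loop, which the tests exploit.  Raster I/O uses the plain-text ESRI
ASCII grid format (square cells), preserving the grid spec and nodata.

Nodata handling: invalid pixels are excluded from numerators and
denominators of fractions and means, and excluded from sums (not treated
as zero).  A coarse cell is set to nodata when its valid-pixel coverage is
below `coverage_min`.  Defaults: 0.5 for fractions, threshold-fractions
and means; 0.0 for sums, so that summed layers (population, radiance)
conserve totals exactly — a cell-level coverage mask would silently drop
mass.  Both choices are parameters.

## Indicators

Six land-cover fractions use Copernicus-style class codes: built-up {50},
forest {111–116, 121–126}, crop {40}, grass {30}, permanent water {80},
and seasonal water, which has no published code in the source class table;
the package defaults to 90 (herbaceous wetland) and flags the choice as
configurable.  Spectral indices are computed at fine resolution and then
aggregated ("percent area with index over t" semantics), never on
pre-aggregated bands.  NDWI uses the McFeeters (Green−NIR)/(Green+NIR)
open-water variant, consistent with a water index thresholded at 0.3; the
Gao NIR−SWIR variant measures vegetation moisture instead and would pair
with a different threshold.  "Over" thresholds are strict (>); boundary
pixels are measure-zero in continuous data, so the choice is documented
rather than consequential.  `ndbi_mean` averages all valid pixels with no
threshold.

## Connectome metric

FNC is the Pearson correlation matrix of the 53 ICN time courses (T ≥ 3,
constant rows rejected by name).  The graph is kept fully weighted — no
proportional thresholding.  Correlations map to weights as |r| by default
(`positive` mode, max(r, 0), is exposed as an alternative since published
pipelines differ in their negative-correlation policy), normalized by the
maximum off-diagonal weight.  The per-node coefficient is the Onnela
geometric-mean triangle intensity

    C_i = Σ_{j≠h} (w̃_ij w̃_jh w̃_ih)^{1/3} / (k_i (k_i − 1)),

k_i = number of nonzero-weight neighbors, C_i = 0 when k_i < 2.  This is
the most common weighted generalization in connectomics toolkits (it is
also what networkx implements, which the tests use as an independent
cross-check), reduces to the binary clustering coefficient on {0,1}
weights, and is bounded in [0, 1] after normalization.  The subject-level
brain outcome is the unweighted mean of C_i over the 7 DMN nodes, computed
on the full 53-node graph.

## Association design

For each indicator × outcome, a linear mixed model is fitted by REML
(statsmodels MixedLM): fixed effects are the z-scored indicator, age
(months) and sex, plus household income and parental education in the
with-SES model set; random intercepts for site and for family nested in
site (site as the grouping factor, families as a variance component).
One indicator per model — the indicators are collinear by construction, so
a joint model would be uninterpretable.  Wald p-values; labels use the
Bonferroni threshold α/11 with α = 0.05 (≈4.5e-3) and a trending band up
to 0.01.

"% variance" is the difference in Nakagawa marginal R² — var(Xβ̂) over
var(Xβ̂) + σ²_site + σ²_family + σ²_resid — between the full fit and a
reduced fit without the indicator, floored at 0, signed by the indicator's
beta.  This definition is pinned because several inequivalent definitions
circulate; a semi-partial-correlation² alternative would give similar
magnitudes for small effects.

## Synthetic worlds

The generator produces every input with known ground truth
(`SimulationTruth`), so planted effects can be recovered end to end.

* **Land cover**: block-partition sampling — 8×8-pixel super-blocks each
  drawn once from the class mixture.  This gives spatial autocorrelation
  (1 km cells differ in composition) while keeping class frequencies
  exactly analyzable.  Default mixture: forest 0.25, crop 0.20, built-up
  0.25, grass 0.15, seasonal water 0.10, permanent water 0.05.
* **Nighttime lights**: gamma noise (shape 3) around class means — 40
  nW/cm²/sr over built-up, 1 elsewhere, the order of magnitude of annual
  VIIRS composites over US cities vs countryside.
* **Population**: class-weighted allocation (built-up 20 : crop/grass 2 :
  other 0.5 : water ~0) with gamma heterogeneity, normalized to sum exactly
  to the requested total (250 000 by default), so conservation holds by
  construction.
* **Reflectance**: class-conditional band means (documented in
  `synth._default_band_means`) ± Gaussian noise (sd 0.02), clipped to
  [0, 1]; vegetation classes sit above the NDVI 0.2 threshold, open water
  above the NDWI 0.3 threshold, and built-up has NDVI < 0.2 and NDBI > 0.
* **Cohort**: 21 sites by default (typical of large US multi-site child
  cohorts), families of 1–3 nested in sites, 1–3 addresses per subject
  (probabilities 0.6/0.3/0.1) scattered around site centers.  Outcomes
  follow the same mixed model the analysis fits: planted betas act on
  z-scored indicator exposures (so fitted standardized betas estimate the
  planted values directly), plus optional direct SES effects, site
  (sd 0.3), family (sd 0.5) and residual (sd 1.0) Gaussian terms.  The
  CBCL-like score is rounded and floored at zero — a linear model is fitted
  to it downstream, mirroring common practice, so no count model is used.
  SES ordinals (income 1–10, education 1–5) are discretized latent normals
  coupled to built-up exposure with correlation ρ = 0.4 (negative
  direction), which reproduces the exposure–SES multicollinearity that
  motivates the dual model sets.
* **ICN time courses**: one shared latent factor per subject; DMN nodes
  load 0.6 + β_dmn·exposure, other nodes 0.25 + 0.4·β_dmn·exposure
  (floored at 0), plus unit white noise, T = 150 frames.  Higher exposure
  raises within-DMN and DMN-to-rest correlations and hence the DMN
  clustering coefficient, monotonically in expectation.

Planted defaults: β(NDBI → cognitive score) = −0.15 outcome SD-units per
exposure SD and β_dmn(NTL → DMN coupling) = 0.06 loading units per exposure
SD.  Both were sized once by a prospective power analysis at the package's
reference design (n = 2000, 21 sites, with-SES models, Bonferroni 0.05/11)
to be comfortably detectable — the synthetic analogue of effects a
well-powered cohort would flag — and are not tuned thereafter.

Every generator is a pure function of (parameters, seed); child streams
are derived from the truth seed per stage.

## What the synthetic worlds do and do not show

They exercise the full computational chain: exact aggregation, linkage
bookkeeping, metric computation, model fitting, label logic, confounding
attenuation, and sign/significance recovery of planted effects.  They do
not emulate real geography (no census-tract structure, no realistic NTL
skew across metros), real fMRI noise (only second-order correlation
structure), non-Gaussian outcome residuals, or missing-data mechanisms
beyond out-of-extent/nodata lookups.  Passing tests therefore validate the
machinery and its statistical calibration, not any empirical claim about
real cohorts.

## Problem sizes and runtime choices

The test suite and acceptance script use sizes chosen to make their checks
informative at interactive cost: zonal and clustering oracles on ≤50×50
rasters and 5–10-node graphs (exact checks need no scale), null
calibration over 200 cohorts of n = 500 (test) or 100 cohorts (script),
and planted-effect recovery over 50 seeds (test) or 20 seeds (script) at
n = 2000 on a 240×240 fine grid.  The default analysis world uses 1000
subjects.

## Known limitations

* Only exact-nesting harmonization; real products need prior resampling.
* ESRI ASCII I/O requires square cells and carries the CRS only as a
  string.
* Wald p-values from REML fits carry no small-sample correction
  (Satterthwaite/Kenward-Roger); with 21 sites the null-calibration check
  keeps the empirical type-I rate inside the binomial band, but batch-level
  wobble around the nominal level remains.
* The exact negative-weight policy and clustering formula used by any
  particular published connectome pipeline may differ; both weight modes
  are exposed and the formula above is pinned.
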