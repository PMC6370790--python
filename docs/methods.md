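# Methods

This note documents the models, numerical choices and limitations of the
melanomap pipeline: what each stage computes, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Trait extraction

**Colour lightness** of a specimen is the grand mean, in double precision,
of all red, green and blue channel values over the region of interest
(ROI); since the three channels share the mask this equals the mean of
per-channel means. Values live in [0, 255] (0 = black, 255 = white) and
are inversely related to melanisation. An empty mask is an error, never a
default value.

**Region of interest.** The thermoregulatorily relevant region is the body
plus the third of each wing closest to it. "Closest third" is
operationalised as a distance-along-axis rule: each wing carries a base
landmark (junction with the body) and a tip landmark, and a wing pixel
belongs to the ROI when the scalar projection of its centre onto the
base→tip axis is ≤ 1/3 of the axis length. An area-fraction rule would
also be defensible; the axis rule was chosen because it is well defined
for any wing shape, matches the notion of proximity to the body, and is
independent of wing-outline digitisation detail. Masks are otherwise
first-class inputs — in a manual-cropping workflow the mask *is* the
protocol — and `build_roi_mask` exists as a geometric helper for
landmarked images. Background pixels are never special-cased; only the
mask defines the considered area.

**Species values.** Images failing the sex policy (default: keep females
and monomorphic specimens) are dropped; morphs are averaged per side
(unweighted over morphs, images within a morph averaged first); a species
missing either side after filtering is excluded with a recorded reason.
Whether morph averaging precedes or follows side pairing is ambiguous in
manual workflows; this package averages per side first, which uses all
available images. Species complexes are collapsed to one row by unweighted
member means (cross-family complexes are an error) and their ranges are
unioned downstream.

## Grid, presence and assemblages

The grid is square (50 km default) in a projected equal-area plane, with
the origin snapped down to a multiple of the cell size so the tessellation
is reproducible without a reference file; cells are half-open so the grid
is a partition (boundary points belong to the lower-left cell). Only cells
overlapping the analysis extent with positive area are kept.

Presence uses a *positive-area overlap* rule (not centroid-in-polygon):
expert range maps over-cover, and any overlap is evidence of presence at
50 km grain. A polygon touching a cell only along its boundary is absent.
The assemblage trait of a cell is the unweighted mean lightness of the
present species (presence data carry no abundances); with a family scope
both the species set and the richness filter restrict to that family.
Cells with fewer than `min_richness = 5` in-scope species are excluded and
counted, which stabilises the mean.

Quantile maps bin cell values at the 1/k … (k−1)/k sample quantiles, ties
to the lower bin, red = lightest, blue = darkest; the default k = 10 is a
display choice only.

## Environment

Annual value = unweighted mean of the 12 monthly layers (hours within a
month averaged first, where hourly layers exist, including night hours for
insolation — configurable). Equal month weights are the simplest defensible
reading of an "annual average". Aggregation to cells is area-weighted over
the pixels a cell covers (robust to resolution mismatch between pixels and
cells); missing pixels are excluded from the weights and a cell with no
data is NaN, never silently zero. All rasters must share the grid's CRS:
the pipeline's data always live in a single projected equal-area plane, so
reprojection is out of scope and a CRS mismatch raises.

## The model battery

For each continent × scope ("all" + each family) × side × variable, OLS
linear and quadratic models are fitted with internally z-scored predictors
(numerical stability of the x² term; r², signs and p-values are invariant
to this). Classification:

- **n.s.** if neither model's overall F-test reaches p < α (α = 0.001).
  The significance level is applied to the overall F rather than to
  individual coefficients — the simplest rule that covers both quadratic
  coefficients at once.
- **U / hump** (by the sign of the x² coefficient) when
  Δr² = r²_quad − r²_lin is *strictly* greater than 0.1; the boundary
  case is linear.
- **linear** otherwise, signed by the slope.

Nestedness guarantees Δr² ≥ 0; the implementation asserts this and treats
sub-tolerance negative values (float fuzz on degenerate data) as zero. A
scope whose assemblage values are constant — e.g. a family represented by
one species everywhere — cannot be fitted and is recorded as *absent*,
never silently skipped; the full two-continent design therefore always
yields 60 records. No multiple-testing correction is applied across the
battery; the 60 models are reported as-is and readers should treat
marginal p-values accordingly.

## Spatial GLS

Errors are modelled with a Gaussian correlation structure on Manhattan
distances, corr(i,j) = exp(−(d_ij/ρ)²), d_ij = |Δx| + |Δy| in km, with ρ
estimated by maximum likelihood (profile over ρ; β and σ² solved in closed
form given ρ).

Two numerical facts shape the implementation:

1. **The kernel is not positive definite.** The Gaussian form is a valid
   covariance for Euclidean distances but not for the Manhattan metric: on
   a regular lattice the correlation matrix acquires substantially
   negative eigenvalues once ρ exceeds the cell spacing. The likelihood is
   therefore evaluated through an eigendecomposition with eigenvalues
   clipped to a small positive floor (10⁻¹⁰ of the largest) — i.e. the
   likelihood of the nearest positive-definite matrix with this structure.
2. **The profile likelihood is multimodal** near singular fits, so the
   optimizer is a coarse log-spaced grid over ρ (20 points between 0.1× the
   smallest and 3× the largest inter-point distance), followed by bounded
   local refinement. With `nugget=True` a nugget variance is estimated
   jointly over a small grid {0.01, 0.05, 0.2, 0.5}; by default the nugget
   is off (a 10⁻⁶ floor keeps the matrix workable). Failure to find a
   finite optimum raises; there is no silent OLS fallback.

Duplicate coordinates are jittered deterministically by ~1 m using a CRC
of the cell id, keeping the correlation matrix nonsingular without
breaking reproducibility. Because dense-covariance ML is O(n³), fits on
more than `max_n` cells (default 3000 at the function level; the pipeline
driver uses 400) run on a seeded random subsample, recorded in the output.
The GLS mean model is linear by default; set `quadratic=True` to match a
quadratic OLS classification.

## Tukey HSD contrasts

Dorsal/ventral and family contrasts use all-pairs Tukey(–Kramer) HSD on a
one-way family × side layout of species-level values:
q = |m_i − m_j| / √(MSW/2 · (1/n_i + 1/n_j)) referred to the studentized
range distribution with k groups and N − k error degrees of freedom
(`scipy.stats.studentized_range`). The "all" dorsal–ventral contrast comes
from a separate two-group test. Groups with fewer than two members are
excluded with a warning. The reported `difference` is ventral − dorsal:
positive when the ventral side is lighter (countershading). This direct
computation reproduces `statsmodels`' `pairwise_tukeyhsd` p-values (the
test suite cross-checks them) and avoids that routine's numerically
inverted confidence bounds, which dominate runtime in simulation studies.

## Synthetic worlds

The generator reproduces the *statistical structure* the analysis assumes,
not the appearance of real data:

- **Climate.** TMP is a north–south linear gradient (defaults 25 °C at the
  southern edge to −5 °C at the northern) plus Gaussian-filtered white
  noise (sd 1 °C, smoothing 3 px) — a separable construction that creates
  spatial autocorrelation cheaply without a full geostatistical model. INS
  is a positive affine function of TMP (150 + 5·TMP W m⁻², noise sd 5) and
  HUM a negative one (75 − TMP %, clipped to [0, 100]), so the three
  predictors are realistically collinear. Monthly layers add a spatially
  constant, zero-mean seasonal sinusoid (amplitudes 8 °C, 40 W m⁻², 4 %),
  making annual averaging non-trivial but exact.
- **Species.** True dorsal lightness is uniform on the integers in
  [60, 200] (8-bit scans quantise to integers, and integer truth makes the
  noiseless render→extract round trip exact); ventral = dorsal + 30
  (lighter below, the countershading pattern), clipped to [0, 255].
  Thermal optimum = mean gradient temperature + β·(lightness − midrange) +
  N(0, 2 °C), with β = 0.12 °C per lightness unit — light species in warm
  climates. Setting `response` to `hump` or `U` inverts the coupling:
  optima uniform over the gradient, lightness a quadratic function of the
  optimum, for shape-recovery checks. Families are drawn with proportions
  0.35/0.35/0.10/0.20 (Lycaenidae/Nymphalidae/Papilionidae/Pieridae),
  roughly the relative richness of the four major families; 15% of species
  get two morphs, rendered at ±4 lightness units so the morph mean equals
  the species truth.
- **Ranges** are the polygonized union of raster pixels within
  niche_width/2 (default 6 °C) of the species' optimum — climate-threshold
  bands with no dispersal or occupancy model, sufficient to couple
  presence structure to climate. Empty ranges are allowed and flagged.
- **Specimens** are rendered as a body ellipse plus four wing quadrangles
  on a white background (default 320 × 440 px, ROI ≈ 19,000 px). ROI
  pixels carry the species' true lightness for that side; the distal wing
  two-thirds carry truth + 40, so any mask error shifts the extracted
  value detectably. Gaussian pixel noise (default sd 3) is added inside
  the specimen, rounded and clipped. The exact ROI mask is emitted
  alongside each image. The generator's point-in-polygon rasterisation
  (shapely, pixel centres) and `build_roi_mask`'s (matplotlib path) are
  independent implementations of the same rule; polygon vertices are
  fractional so no pixel centre lies on an edge.

All randomness flows from one integer seed through named SeedSequence
sub-streams (climate variables, pool, per-species × side × morph renders),
so identical configs give bit-identical rasters, polygons and images.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: real wing patterning and segmentation error,
sexual dichromatism beyond a tag, intraspecific and geographic trait
variation, range shapes decoupled from climate (dispersal limits,
biogeographic history), coastlines and irregular extents, non-stationary
or anisotropic spatial autocorrelation, and observation error in atlas
presence data. Tests demonstrate that the *pipeline computes the intended
quantities correctly*, not that the ecological conclusions would survive
those complications.

## Problem sizes

Default analysis runs use two 2,000 × 1,500 km continents at 25 km raster
resolution (80 × 60 pixels), 120 species each, and a 40 × 30 grid of 50 km
cells (1,200 cells, ~1,170–1,190 retained by the richness filter); GLS
fits subsample to 400 cells. Replicated recovery checks use 600 × 400 km
worlds with 40 species. These sizes give stable estimates (assemblage
means over ~50 species per cell; regression n > 1,000) while keeping a
full run in seconds.

## Known limitations

- The GLS is exact ML only up to the positive-definite projection of the
  (indefinite) Gaussian–Manhattan kernel; ρ̂ should be read as a
  correlation-range summary, not a consistent estimate of a generative
  parameter, except when data were generated under the same projected
  family (as in the recovery tests).
- The battery's r² values on default synthetic worlds are higher
  (≈ 0.97–0.99) than typical field data because assemblage averaging over
  many species suppresses trait noise and the generator's climate–trait
  coupling is exactly linear.
- `run_pipeline` orchestrates synthetic worlds only; real-data runs
  compose the same stage functions (`stage_traits`, `stage_grid`,
  `stage_environment`, `stage_stats`) on inputs loaded through the
  documented file interfaces, or use the per-stage CLI.
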