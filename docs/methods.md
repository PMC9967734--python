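# Methods

This note documents the models implemented in `greenrisk`, the defaults
they ship with, and the choices made where the underlying methodology is
genuinely open.

## Synthetic landscapes

The generator exists so every downstream estimator can be verified
against known ground truth. A base land-cover grid is built by drawing
Gaussian white noise, convolving it with a Gaussian kernel whose σ is the
configured autocorrelation range (default 6 cells), and thresholding the
ranked field at the quantiles implied by the class proportions. The rank
transform makes the realized class proportions exact to grid granularity,
and the smoothing produces contiguous patches whose same-class join
fraction exceeds the random expectation Σp².

Defaults describe a 300 × 300 grid at 1 km resolution — large enough for
law-of-large-numbers parameter recovery and landscape-metric stability,
small enough that the full pipeline runs in seconds. The default class
mix (cultivated 0.38, forest 0.34, grassland 0.08, water 0.04,
construction 0.10, unutilized 0.06) is a cultivated/forest-dominated
cold-temperate province in broad strokes. The default ground-truth
transition matrix is persistence-dominated with agricultural expansion
(inflow to cultivated from forest, grassland and unutilized land),
moderate construction growth and retreat of forest and unutilized land,
so that all three green-space evolution types occur with workable
frequencies in a single model period.

The second epoch is drawn cell-wise from the ground-truth matrix
(independent multinomials given the base map), which is exactly the
sampling model under which the transition estimator is consistent: the
suite checks elementwise recovery within ±0.03 for rows with ≥ 500
source cells.

Drivers are smooth random fields with the named roles rather than
physical simulations: elevation mixes short-range relief into a
long-range trend scaled to 0–1350 m so that a small tail of 1-km cells
exceeds the 15° policy threshold; slope is the finite-difference gradient
of elevation in degrees; road distances are Euclidean distance transforms
of random polylines; population and GDP are log-normal fields amplified
×3 inside a random "urban" disc so construction suitability has a
spatial signal. The black-soil mask is the set of cells nearest a random
centre, contiguous by construction with an exact area fraction (default
0.25). What the generator does *not* emulate: realistic topography or
climate gradients, road network topology, settlement structure along
roads, or any calibration to a real province. Passing tests therefore
demonstrate correctness of the estimators and bookkeeping under the
stated statistical assumptions, not predictive skill on real rasters.

## CA–Markov projection

Demand: class targets after `steps` periods are the epoch counts times
the `steps`-th power of the estimated transition matrix, rounded by
largest remainder so targets sum exactly to the valid-cell count. No
annualization (matrix root) is attempted — roots of empirical stochastic
matrices need not exist or be stochastic — so the projection horizon is a
whole number of estimation periods.

Allocation: each of 10 iterations allocates an equal share of each
class's remaining net demand. Candidates are scored by suitability ×
neighbourhood density (fraction of the 5 × 5 window already in the
class, plus a 10⁻⁶ floor so positive-suitability cells with empty
neighbourhoods remain eligible); permitted candidates convert in
descending score order, drawing only from classes currently above their
target, with seeded random jitter (≤ 10⁻¹²) breaking ties reproducibly.
Classes are processed in descending-demand order within an iteration.
This greedy rule is deliberately simple, deterministic and auditable;
it is not a numerical replica of any proprietary desktop implementation.
If constraints make targets unreachable the allocator stops at the
feasible boundary and warns with the shortfall — it never violates a
mask. Nodata cells are frozen and excluded from every count.

Suitability: each driver is min–max rescaled, oriented per class (e.g.
cultivated suitability falls with slope, construction suitability falls
with road distance; the full orientation table is
`lucc.DEFAULT_ORIENTATIONS` and overridable), combined as a weighted
linear sum — default equal weights over the nine drivers, as no weighting
scheme is prescribed — and multiplied by the class's constraint mask.
The NP and BCU scenarios share the suitability construction and differ
only in the constraint masks.

Constraint semantics: masks forbid *conversion to* a class at a cell;
keeping one's class is always allowed. Under BCU, a flat cultivated cell
has no permitted outbound conversion (frozen), while a steep (> 15°)
cultivated cell may convert only to forest or grassland.

## Carbon accounting

Straight density bookkeeping: per-class total density is the exact sum of
the four pools; a 1 km² cell carries 100 ha × density tonnes. The default
density table (t/ha) is a compilation for a cold-temperate black-soil
region and is deliberately swappable via CSV, since such densities are
region-specific estimates. One structural consequence worth knowing:
water's total density (33.94 t/ha) is *below* construction (42.08) and
unutilized land (54.82), so green-space loss from water bodies gains
carbon under this table; the vegetated green classes all lose. Carbon
change totals are aggregated by evolution type and partition the total
change exactly. Within-class density variation is out of scope.

## Landscape ecological risk

Plots are axis-aligned squares (default 20 km) clipped to the data
footprint; plots with < 10 % valid cells are dropped rather than padded,
which avoids inflated separation indices on ragged borders. Patches are
8-connected components *within* a plot (the common landscape-metric
default). Grid-wide quantities — total area A, total patch count N,
number of plots M, occurrence counts m_i — are computed over the full
retained grid; n_i, A_i and the plot area A_n are per plot.

The loss index is R_i = I_i × E_i, reading the disturbance index I_i as
the per-class degradation term (the conventional composition of this
family of indices), with I_i = 0.5·fragmentation + 0.3·separation +
0.2·dominance and E_i the fixed rank-normalized vulnerability constants
(rank/21; built-up land least fragile, cropland most). Note the published
3-decimal constants sum to 1.001 because of print rounding; the forest
value 4/21 = 0.1905 is one print-unit below its published 0.191.

Interpolation is ordinary kriging at plot centroids: empirical
semivariogram in 12 equal lag bins to half the maximum distance,
spherical model fitted by weighted least squares with Cressie weights
(pair count over squared model value), γ(0) = 0 so the predictor honours
the data exactly even with a fitted nugget. A singular system falls back
to inverse-distance weighting (power 2) with a warning; a constant field
short-circuits to a constant surface. Five risk bands come either from
fixed reporting thresholds (0.010 / 0.012 / 0.013 / 0.015) or from Jenks
natural breaks — an exact O(kn²) dynamic program, fitted on a seeded
subsample of at most 3000 values for large surfaces (the usual desktop
practice) and verified against exhaustive partition search at small n.

## Coupling coordination

W (carbon) and S (risk) are min–max normalized over the pooled set of
units being compared; the pool is recorded in the output metadata because
D values are only comparable within a pool. In the pipeline the pool is
all sampling plots across all epochs/scenarios, and each epoch is scored
at its plot means; this keeps every epoch's (W, S) interior to [0, 1]
rather than pinning the extreme epoch to 0 as a three-row pool would.
Risk is *not* inverse-oriented by default: the published worked rows are
reproducible only with direct orientation (the option exists). α = β =
0.5. Reported scores are rounded half-up to 3 decimals. C is undefined
at W = S = 0 and returns 0 with a warning.

## Bivariate spatial correlation

The normality gate is a one-sample K–S statistic against a normal with
the sample's mean and SD; because the parameters are estimated from the
same data the p-value is computed by seeded Lilliefors Monte Carlo
(10⁴ replicates by default). Spearman's ρ is the Pearson correlation of
mid-ranks.

Weights are queen contiguity on the plot grid (the usual desktop
default; the method text names only "adjacency"), row-standardized;
islands are flagged. The global bivariate statistic is implemented
verbatim as I = n·ΣΣW_ij·Qk_i·Ql_j / ((n−1)·ΣΣW_ij) with population-SD
z-scores — note the (n−1) in the denominator, kept for fidelity to the
source formula; a `geoda_style` toggle computes the conventional
mean(Qk·lag(Ql)) cross-Moran for comparison with other software. The
subsystem z-scores use the SD (the source text says "variance" but the
statistic is scale-free only with the SD). Local values are
I_i = Qk_i·Σ_j W_ij·Ql_j, with the focal unit's own value indexing the
first factor.

LISA significance uses conditional permutation: the focal Qk_i is held
fixed, the other units' Ql values are reassigned to its neighbours
(seeded draws without replacement, shared permutation pool across units),
and the pseudo p is (#{|I_perm| ≥ |I_obs|} + 1)/(n_perm + 1) — two-sided,
since both positive and negative clusters are reported. Significant units
are labelled by the quadrant of (Qk_i, lag of Ql); no multiple-testing
correction is applied by default (an FDR flag exists). Under independent
noise fields the realized type-I error sits at the nominal α (checked at
n = 400, 20 seeds).

The analysis units for the change-correlation stage are the 20 km plots
(configurable): per plot and evolution stratum, the mean per-cell carbon
change and mean interpolated-risk change over that stratum's cells;
plots with fewer than 3 stratum cells are dropped, and a stratum is
reported only with ≥ 12 plots.

## Pipeline, determinism and problem sizes

Every stochastic stage derives its seed deterministically from the run
seed, so identical (config, seed) produce byte-identical CSV outputs;
each output embeds the config hash (computed over everything except the
output path) and seed. The bundled demo and the test suite run the full
pipeline at 120 × 120 cells; parameter-recovery and calibration tests
use the 300 × 300 default. The written bundle uses ESRI ASCII grids,
GeoJSON, CSV and a markdown summary.

## Known limitations

- The CA allocates *net* demand only; gross churn below the net (e.g.
  simultaneous loss and gain of the same class in different places
  beyond demand) is not simulated, so projected exchange/loss areas are
  conservative relative to a process with independent cell-level
  transitions.
- Landscape indices are computed on plot-clipped patches; patches
  spanning plot boundaries are counted in each plot.
- The vulnerability ranking and disturbance weights are fixed constants
  from the source methodology, not fitted quantities.
- Synthetic drivers carry no real geography; see the synthetic-landscape
  section for what passing tests do and do not establish.
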