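# Methods

This note documents the models, conventions and numerical choices behind
fire-equity, and what the synthetic validation does and does not establish
about real data.

## Hazard surface

The hazard input is a single-band regular grid with a nodata/non-burnable
mask. Values are mapped linearly from a stated input range onto [0, 1];
masked cells become 0 ("unburnable") but keep their flag. Tract hazard
(WHP) is the arithmetic mean over cells whose **centers** fall inside the
tract polygon. Cell-center membership was chosen over area-weighted overlap
because it partitions the cells exactly and introduces no overlap-geometry
tolerance; at 270-m-class resolutions the difference is confined to boundary
cells. Ownership of a center lying exactly on a shared edge follows a
half-open rule: the center belongs to the polygon containing the point
nudged toward the lower-left (implemented with a nudge of 10⁻⁶ cell sizes),
so in any tessellation every center is counted exactly once. Non-burnable
cells contribute 0 to the tract mean by default — unburnable land inside a
tract genuinely dilutes its exposure — with a flag to exclude them instead.
Tracts containing no centers get a missing mean and a warning rather than an
error.

The at-least-moderate exposure filter keeps tracts with mean hazard ≥ 0.4
(inclusive). The 0.4 default is the lower edge of the middle class when the
five burnable classes (very low … very high) are spaced uniformly on [0, 1];
real hazard products bin non-uniformly and do not publish a single boundary,
so the threshold is a configuration parameter, not a constant.

## Adaptive-capacity index

Thirteen indicators in four domains are combined by rank → percentile rank →
sum → percent rank. The percent-rank convention is (r − 1)/(N − 1) with
average ranks for ties, so the index runs exactly from 0 (greatest capacity)
to 1 (least). All indicators are oriented so that larger oriented values
mean lower capacity; per-capita income is the one default higher-is-better
indicator and is negated before ranking. The default indicator set
(% below poverty, % unemployed 16+, per-capita income, % without a
high-school diploma, % limited English, % 65+, % 17 and under, % disabled,
% single-parent households, % mobile homes, % multi-unit housing, % renters,
% without a vehicle) is a documented, configurable stand-in for an
ACS-derived list.

Numerically, the final re-rank is computed from the sum of the **raw**
average ranks rather than the scaled percentile ranks. Raw average ranks
are half-integers and therefore exact in floating point; summing scaled
ranks can split exact ties differently under different affine percentile
scales (0–1 vs 1–100) through rounding alone. With the raw-sum construction
the index is provably identical under any positive affine intermediate
scale, and the test suite asserts this equality bitwise. Constant indicator
columns are permitted (everyone ties; the column contributes nothing) with a
warning; missing values are rejected, naming the offending tract.

## Vulnerability score and quadrants

V = √((AC − AC_min)² + (WHP − WHP_min)²), with the origin offsets taken as
the observed minima over the filtered subset by default (the plotted space),
switchable to global minima. Quadrant splits default to AC = 0.5 (the
midpoint of the percent-rank scale) and WHP = (threshold + 1)/2 (the
midpoint of the retained hazard range); neither boundary has a canonical
published value, so both are parameters. The quadrant letters follow the
geometric rule (high hazard, low deficit) → A, (high, high) → B,
(moderate, low) → C, (moderate, high) → D, with boundary points classified
upward (≥). Representation ratios divide a group's population in a quadrant
by the group's grand total over **all** tracts, so the ratios also reflect
how much of each group survives the exposure filter; the expected share is
the quadrant's total population over the same grand total.

## Quantile regression

The disparity model Q_τ(V | x) = β_τ0 + β_τ1·x is fitted by exact linear
programming: minimize τΣu⁺ + (1−τ)Σu⁻ subject to
β_0 + β_1·x_i + u_i⁺ − u_i⁻ = y_i, u± ≥ 0, solved with HiGHS through
`scipy.optimize.linprog` with the intercept and slope split into positive
parts. This attains the global check-loss minimum deterministically; the
test suite verifies the objective against a brute-force enumeration of all
lines through pairs of observations (the LP optimum interpolates at least
two points in nondegenerate cases) and checks the residual-sign optimality
condition (at most a τ fraction of strictly negative and a 1−τ fraction of
strictly positive residuals) on every fit. The default predictor is the
group's tract **proportion**; raw counts are available by flag since both
parameterizations are defensible and they answer slightly different
questions. Standard errors are a pairs bootstrap (resample (x, y) tuples,
refit, take the SD of the coefficients; resamples with constant x are
redrawn, at most 10 times). Degenerate designs (constant x, n < 3) raise
typed errors rather than returning nonsense.

The dispersion diagnostic reports the coefficient of variation of V (sample
SD over mean) among tracts with x ≤ min(x) + 0.25 and x ≥ max(x) − 0.25;
the window is absolute on the proportion scale and configurable. Group
share vs AC and vs WHP associations are plain Pearson correlations.

## Synthetic-data generator

The generator provides a world in which every downstream estimate has a
known target.

* **Hazard field:** i.i.d. standard-normal noise, Gaussian-smoothed with a
  configurable sigma (default 5 cells) and min-max normalized to [0, 1]. A
  sigma of 0 gives spatially independent values (Moran's I ≈ 0); sigma 5
  gives strong positive autocorrelation (Moran's I > 0.5 at 100×100). A
  configurable fraction of cells (default 5%) is flagged non-burnable. This
  is a statistical landscape, not fire-behavior physics.
* **Tracts:** an exact rectangular tiling of the raster extent (default
  50×50 tracts over a 200×200 grid, i.e. 4×4 cells per tract).
* **Demographics:** per-tract Dirichlet compositions over six groups
  (white, black, hispanic, native_american, asian_pacific, other) with
  concentrations (7.0, 1.2, 1.7, 0.25, 0.55, 0.35), giving a realistic
  majority-group skew. Counts are shares × tract population rounded by
  largest remainder, so they always sum to the tract total. Tract totals
  are normal (mean 4,000, SD 1,200, floor 200) — the right scale for census
  tracts, without the long tails of real data.
* **Latent disadvantage:** a scalar factor d built from standardized tract
  hazard, group-share loadings and noise. The noise component is
  residualized against standardized hazard before mixing with weight
  ρ = `disadvantage_hazard_corr` (default 0.6), so the **realized sample**
  correlation between d and tract hazard equals ρ exactly; recovery tests
  therefore measure the pipeline, not Monte-Carlo luck. A single factor
  suffices because the index treats the 13 indicators as exchangeable rank
  inputs. Indicators are loading·d + Gaussian noise (loadings 0.60–1.20,
  noise SD 0.8), passed through monotone cosmetic maps (logistic for
  percentage-type columns, exponential for income) that change appearance
  but not ranks.
* **Heteroscedastic scenario:** y = β0 + β1·x + (σ0 + σ1·x)·ε with ε ~
  N(0, 1), x ~ U(0, 1) (defaults β1 = 1, σ0 = 0.5, σ1 = 1, n = 5,000). The
  true τ-quantile line has slope β1 + σ1·z_τ — the direct oracle for the
  regression stage.
* **Majority-ratio injection:** with `inject_majority_ratio = (group, r)`,
  the generator runs the same AC → filter → V computation the pipeline will
  run, sorts the filtered tracts by V, and assigns majority-group
  compositions to the contiguous V-window of ~25% of tracts whose mean-V
  ratio against the remainder is closest to r (a sliding window sweeps the
  ratio continuously, so the match is essentially exact). Group loadings
  must be zero in this mode, because compositions are assigned after the
  indicators exist. This makes "majority-group tracts have r× the mean
  vulnerability" true **by construction**, so an end-to-end run recovering r
  validates the entire chain.

Everything is a pure function of the config: each component draws from its
own `numpy` generator seeded by (component id, seed), and regenerated
bundles and rerun pipelines are byte-identical.

What passing these tests shows: the index, aggregation, scoring and
regression machinery compute what they claim on data with census-like
*structure*. What they do not show: anything about real ACS margins of
error, real tract geometry, non-uniform hazard class boundaries, or the
magnitude of real-world disparities — those require the real rasters and
tables, which are deliberately out of scope.

## Problem sizes and runtime choices

The standard validation world is 2,500 tracts on a 200×200 grid; the
recovery tolerances used in tests (±0.1 on the injected ratio, ±0.05 on the
injected correlation, 3 Monte-Carlo SEs on quantile slopes over 20 seeds at
n = 5,000) are comfortable at that size. Bootstrap standard errors default
to 200 replicates in the library and 50 in the bundled integration configs;
with six groups and two quantiles the bootstrap dominates pipeline runtime
(each replicate is one LP solve). The zonal-statistics oracle comparisons
use rasters up to 20×20 with up to 9 tracts, where the scalar per-cell
brute force is exact and fast.

## Known limitations

* No CRS handling: rasters and polygons must share a coordinate frame
  already (no reprojection).
* Raster I/O is the ASCII-grid text format only.
* Single-predictor quantile regression; no spatial autocorrelation
  correction of the bootstrap SEs, which will be optimistic when V is
  spatially dependent across tracts.
* The hazard classes are uniformly spaced on [0, 1] by default, which real
  hazard products are not; set the threshold and class bounds to match the
  product in use.
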