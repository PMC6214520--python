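# fire-equity

Social-ecological wildfire vulnerability analysis for census-tract-scale
data. The package is aimed at environmental-justice and hazards researchers
who want to combine a biophysical wildfire-hazard surface with socioeconomic
adaptive capacity, and then ask *who* lives in the most vulnerable places.

## The method

Given a wildfire-hazard raster and a per-tract table of socioeconomic
indicators and race/ethnicity counts, the pipeline computes:

1. **Tract hazard (WHP).** The raster is rescaled linearly to [0, 1]
   (0 = unburnable land) and averaged over the raster cells whose centers
   fall inside each tract polygon. Tracts below a *moderate* hazard
   threshold (default 0.4) are excluded — vulnerability presumes at least
   minimal exposure.

2. **Adaptive-capacity index (AC).** Thirteen indicators in four domains
   (socioeconomic status; language and education; demographics; housing and
   transportation) are each ranked across tracts, converted to percentile
   ranks, summed per tract, and the sums percent-ranked again:

   AC ∈ [0, 1], with 0 the greatest capacity to absorb and recover from a
   wildfire and 1 the least. The index is a pure rank object: it is invariant
   to any strictly increasing transform of an indicator and to the affine
   scale of the intermediate percentile step.

3. **Vulnerability.** Each tract's vulnerability is its Euclidean distance
   from the origin of the AC × WHP plane,

   V = √((AC − AC_min)² + (WHP − WHP_min)²),

   giving hazard and adaptive deficit equal weight. One split per axis
   partitions the plane into quadrants A (high hazard, low deficit),
   B (high, high), C (moderate, low), D (moderate, high).

4. **Representation ratios.** For each quadrant and group: the share of the
   group's total population living there, compared with the quadrant's
   overall population share (the value expected if all groups were
   distributed alike).

5. **Disparity regression.** For each group, the conditional quantile lines
   Q_τ(V | x) = β_τ0 + β_τ1·x at τ = 0.05 and 0.95, with x the group's tract
   proportion (or count), fitted by exact linear-programming minimization of
   the check loss Σ u(τ − 1[u<0]); pairs-bootstrap standard errors; plus the
   coefficient of variation of V among the tracts with the lowest/highest
   group proportions, and Pearson correlations of group share with AC and
   WHP.

Because real census and hazard rasters are large external datasets, the
package ships a synthetic-data generator with fully known structure — a
smoothed-Gaussian hazard field, a rectangular tract tessellation, Dirichlet
demographics, and indicators driven by a latent-disadvantage factor with an
exactly injected hazard correlation — so the entire chain can be validated
against recoverable ground truth.

## Worked example

`examples/05_full_pipeline.py` generates a 100×100 raster tiled by 625
tracts with a known 1.5× majority-group vulnerability ratio built in, writes
it to disk, and runs the full pipeline on the files:

```
tracts: 625, at/above moderate hazard: 527, quadrants: {'A': 11, 'B': 82, 'C': 214, 'D': 220}
mean vulnerability, majority-group vs other tracts: 1.499 (constructed: 1.499)
native_american tau=0.05 slope: +0.735 (SE 0.025)
```

The measured 1.499 recovers the constructed ratio through the whole chain;
the positive 0.05-quantile slope says the *minimum* vulnerability a tract
experiences rises with that group's population share — the "upward
compression" signature. `examples/04_quantile_disparity.py` does the same
for the closed-form scenario y = x + (0.5 + x)ε, whose true tail slopes are
1 ± 1.6449:

```
tau=0.05: slope -0.588 (SE 0.187), analytic -0.6449, check loss 151.4, n=1500
tau=0.95: slope +2.692 (SE 0.204), analytic +2.6449, check loss 160.7, n=1500
```

The remaining examples walk through each stage in isolation. A thin CLI
wraps the same library calls:

```bash
fire-equity simulate --config sim.yaml --out bundle/
fire-equity run --config run.yaml
fire-equity report --run out/        # vulnerability plane, ratio bars, quantile fans
```

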