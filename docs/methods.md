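# Methods

This note records the models, conventions and design choices behind
`perisurf`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Height maps and preprocessing

A height map is a rectangular grid of surface heights (μm) at a uniform
lateral step (the instrument context is a structured-light profilometer
scanning at a 5 μm step with a sub-micrometre vertical resolution and a
Z-range of order 800 μm).  Files are plain text: an `ascii-grid` dialect
with a three-line header (magic line; rows/cols; step sizes, units,
missing-point sentinel) or a bare CSV matrix with a `.meta` sidecar.
Proprietary instrument formats are out of scope.

Scans whose missing-point fraction reaches 10% are rejected, mirroring the
retention rule used for field scans.  Surviving missing points are filled
by bilinear interpolation from valid neighbours (nearest-valid at the
boundary).  Levelling removes the least-squares plane; all parameter
computations assume the levelled, fully-valid map with mean height 0.  The
levelling operator is a package convention — standard in areal texture
analysis — since no form-removal settings accompany the study context;
preprocessing is idempotent by construction.

Mesh export builds a watertight solid (grid top surface, flat base at a
configurable thickness, stitched side walls) in mm for material-jetting
fabrication of 50 × 50 mm growth tiles.  Watertightness and Euler
characteristic 2 are asserted in tests via trimesh.

## Areal texture parameters

Only two definitions are anchored explicitly in the source context — the
areal material ratio at the mean height, Smr = 100·A(m)/A(N), and the mean
absolute height Sa.  The remaining 24 parameters follow ISO 25178-2
definitions with ISO-conventional defaults:

* material at a section c is counted where z ≥ c (ties included), so a flat
  surface has Smr = 100%;
* the material ratio curve is the exact empirical curve over all sorted
  heights; its inverse c(p) interpolates linearly between sorted points;
* Smc at material ratio 10%; Sxp = c(2.5%) − c(50%);
* volume parameters at p = 10%, q = 80%, computed per unit area as means of
  (z − c)₊ and (c − z)₊ — exact discrete integrals, not curve-resampled;
* the Sk family uses the 40%-width minimum-slope secant on the material
  ratio curve sampled at 0.1% resolution; ties pick the first window; a
  degenerate flat curve yields zeros with Smr1 = 0, Smr2 = 100;
* Sal/Str threshold the FFT-based cyclic autocorrelation at s = 0.2,
  walking 360 directions at half-step resolution with bilinear
  interpolation; Sal is the shortest decay radius, Str the shortest over
  the longest (directions that never decay contribute the maximum radius
  reachable in the map);
* Std is the wavevector angle of the spectral maximum, counterclockwise
  from +x, modulo 180°;
* S5p/S5v average the five largest pruned hill peaks / dale pits (all of
  them, flagged, when fewer than five survive); S10z = S5p + S5v.

Every parameter is checked against an independently coded brute-force
evaluation of its definition on small grids to 1e-9 relative tolerance,
and the amplitude-homogeneity and translation-invariance properties are
tested directly.

On a zero-variance surface Ssk and Sku are undefined and raise an explicit
error rather than returning silent zeros.

## Hill/dale segmentation and Wolf pruning

Dales are the catchment basins of z, hills the basins of −z.  The
watershed is deterministic flow-routing: each point descends to the
neighbour minimising the strict lexicographic key (height, row, column);
the strict total order resolves plateaus and ties reproducibly and makes
hill segmentation of z exactly the dale segmentation of −z.  Connectivity
is 8 by default, configurable to 4.  This authored implementation (rather
than a library watershed) is what makes the brute-force label-equality
oracle in the tests exact: vendor watershed tie-breaking is unspecified.

Wolf pruning merges a feature whose Wolf height — |local extreme − lowest
boundary saddle| — is below a threshold into the neighbour across that
saddle.  The threshold defaults to 10% of Sz (the conventional cut between
significant and non-significant features); merges proceed smallest Wolf
height first with label-order tie-breaks, iterating to a fixed point.  The
saddle between two regions is the minimum over adjacent point pairs of the
higher of the two heights.  Pruning is idempotent, and the retained count
is non-increasing in the threshold (both tested).  The phrase "retain
elements below the watershed value" is ambiguous in the source context;
the standard reading — pruning removes small features — is implemented,
and the fraction is configurable.

Site classification is a pure height-threshold rule: hill at ≥ 3000 μm,
dale at ≤ 0 μm, neither in between (both thresholds configurable).

## Pearson-system surface synthesis

The generator targets three parameters at fixed distribution shape.
Given skewness and kurtosis (defaults −0.3 and 3.0, the values observed
on both colonized and bare rock areas), the Pearson criterion selects the
family member; −0.3/3.0 give κ = −0.256, Type I, realized as a
four-parameter beta by closed-form moment matching on the Pearson ODE
coefficients.  Types II/VII/III use their standard closed forms
(symmetric beta, scaled Student t, standardized gamma); Types IV/V/VI fall
back to numerical inverse-CDF integration of the Pearson density.  The
sampler matches all four moments in population and is deterministic per
seed.

Spatial structure: the raw draws are arranged on the grid, Gaussian
low-pass filtered (periodic boundaries; correlation length default 2 mm,
chosen so hill widths land in the ~5–10 mm range on a 50 mm tile), then
rank re-mapped onto the sorted draws.  Rank re-mapping makes the output an
exact spatial rearrangement of the sample, so the marginal — and hence all
four moments — survives filtering exactly.  The mm-scale correlation
mechanism is a package design choice (a standard non-Gaussian rough-surface
construction); the source context states no mechanism.

Calibration is a fixed-point loop (relative tolerance 5%, max 50
iterations), ordered by coupling strength:

1. **Sa** — multiplicative scaling of the overall amplitude σ;
2. **Sv** — a constant h multiplying deviations below the 2% height
   quantile, stretching the deepest pits.  Restricting h to the pit tail
   keeps Sa and the material ratio nearly unchanged (only ~2% of points
   move), decouples the two amplitude targets, and keeps the achieved Sv
   linear in h at frozen σ.  Scaling all below-mean material instead was
   tried and rejected during design: it distorts the marginal's skewness
   and caps the reachable Sv/Sa ratio below the Level-1 design point
   (6.6/0.7 ≈ 9.4).
3. **Smr** — a regular grid of flat-bottomed square depressions (default
   5 mm pitch, depth 0.25 × the Sv target, deterministic per-cell jitter so
   the achieved area fraction varies smoothly on coarse grids); the area
   fraction is adjusted by bisection on the bracket where the measured Smr
   crosses the target.  Note that with depressions much deeper than the
   surface spread, Smr is not globally monotone in the area fraction (the
   mean plane shifts down faster than material is removed at small
   fractions); the bracket search only needs a single crossing, which
   holds for targets below the undepressed material ratio.  Targets above
   the marginal's own material ratio are rejected as infeasible —
   depressions only remove at/above-mean material.

Achieved Sa/Sv/Smr are re-measured each iteration through the parameter
module on the re-levelled surface — never read from the knobs — and
reported as targeted/actual/percent-error, the same layout used to
validate fabricated tiles.  Non-convergence is reported via a flag, never
silently.  The pipeline is bit-reproducible per seed; different seeds give
"self-similar" replicates (different grids, shared parameter values).

Default problem size is a 128 × 128 grid at 0.4 mm step (a 50 mm tile),
which the calibration loop handles in tens of milliseconds; the moment
fidelity checks use 512 × 512.

## Colonization statistics

Screening runs an independent one-way ANOVA per parameter between the
colonized and bare feature groups (two groups, so F = t²), reporting group
means, SDs, F and p, with significance at per-parameter α = 0.05 and **no**
multiple-testing correction by default — matching the per-parameter
reporting convention of the screen this emulates; Bonferroni and
Benjamini–Hochberg are available but off.  Constant columns are flagged
undefined.  Under the null the per-parameter rejection rate is α (tested
at 2000 replicates), and the power of the Smr screen at the configured
group moments matches the analytic noncentral-F power.

The biomass comparison is a one-way ANOVA on treatment level
(df = (g−1, N−g); the reference design gives F[1, 70]), the ratio of level
means, Tukey HSD across flow lanes within each level, and the
Anderson–Darling statistic on the residuals — reported as a diagnostic,
never used to gate the ANOVA.  Trial is carried as a blocking label in the
generated datasets but not modelled.

Hill localization reports the percentage of early-colonization sites whose
height classifies them as hills.  The secondary per-hill ratio
(hills containing ≥ 1 site vs hills with none) is exposed when a pruned
hill feature set is supplied; it has no reference value to compare
against.

## Synthetic data

The generators encode the study conditions as configuration defaults:
21/21 colonized/bare dales with Sv 203.94 ± 49.14 vs 163.63 ± 55.86 μm,
Sa 46.63 ± 12.09 vs 38.24 ± 10.94 μm, Smr 0.001 ± 0.001 vs
0.004 ± 0.002 %; biomass 1.86 ± 0.40 vs 0.50 ± 0.16 mg/cm² over
12 replicates × 3 trials per level on 4 lanes (6 tiles per lane per trial,
3 of each level, alternately placed); hill bias 0.99 for early sites.
The Smr group values are used verbatim as opaque statistics; their scale
is not reconcilable with the synthesis-level Smr targets (30–52%) under
any single convention, so they configure the screening stage only.

Quantities that are physically non-negative are drawn from normals
truncated at zero; the signed skewness column is left untruncated.  The
23 parameters without reported group differences are generated identically
in both groups so the screen's specificity is testable.  Rock-like
surfaces are a noisy plane with non-overlapping cosine-bell pits at
registered centres and drawn depths — the registry is the ground truth for
segmentation-recovery tests.  Pit geometry is a modelling convenience;
only the depth statistics matter to the oracles.

What the generators deliberately do **not** emulate: real mineral
micro-texture and its spatial nonstationarity, instrument noise structure,
fabrication (printing) error — the ~30% Sa/Sv deviations observed on
physical tiles are printing artifacts, not model behaviour — and any
hydrodynamic mechanism behind the hill bias, which is imposed as a
probability rather than simulated.  Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline, not field
validity on real rocks.

## Known limitations

* The Sv targets of the tile designs (6.6–8.4 mm) are treated as abstract
  calibration targets; their geometric relation to tile thickness and flow
  depth is not modelled.
* Sal/Str depend mildly on the angular and radial sampling of the
  autocorrelation walk; the defaults (360 angles, half-step radii) are
  stable well beyond the test tolerances but are conventions, not
  standards.
* The Pearson Type IV/V/VI numerical sampler trades tail accuracy for
  robustness (fixed compactified grids); Type I — the case the synthesis
  uses — is exact moment matching.
* Open (border-touching) and closed dales are not distinguished; motif /
  change-tree analysis is out of scope.
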