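# Methods

This note documents the statistical models implemented in `geohet`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Observed heterozygosity

For a subject subset and loci `j = 1..l`, `H_O = 100 · (1/l) Σ_j h_j`,
where `h_j` is the number of heterozygous calls divided by the number of
non-missing calls at locus `j` within the subset. Loci with no callable
genotype in the subset are dropped from the average rather than treated as
zero; this per-locus complete-case rule keeps `h_j` well defined under the
~97% call rates typical of SNP panels and reduces to the pooled-count
estimator on complete data. Units with no (filtered) subjects are reported
as absent (NaN), never as 0 — a 0 is a real measurement (no heterozygotes).
Genotypes are coded 0/1/2 with −1 for missing; which homozygote is 0 is
immaterial to `H_O` (tested as an invariance).

## Socio-demographic covariates

All covariates are per land unit. Age and education measures
(`AGE25_39`, `AGE40_54`, `AGE55_74` — inclusive bands; `AGE_MEAN`;
`EY8_11`; `EY_MEAN`; `EDU_MEAN`) are computed on the native subset only;
`GER_P` (percent natives) on all subjects; `MAIN_IMP` (percent of the
major immigrant group among immigrants) is defined as 0 for units with no
immigrants, so that summary statistics over units include those zeros
rather than dropping the units. Percentages are kept at full precision
internally; a rounded presentation mode reproduces integer-printed per-unit
tables, and summary statistics computed on those rounded values match the
published summary rows. Model-formula aliases (`BILD_MN`, `EY_MN`,
`AGE_MN`, `EA55_74`) resolve to `EDU_MEAN`, `EY_MEAN`, `AGE_MEAN`,
`AGE55_74`; they are aliases, not distinct variables. The sd uses the n−1
denominator throughout.

## Regionalization and spatial weights

Geometry is planar, in projected meters; geographic inputs must be
projected (e.g. to the data's UTM zone) before use. Contiguity is
queen-style: any shared boundary point makes two units neighbours, with a
snap tolerance (default 1 m) absorbing digitization noise. The boundary
distance used by the isolate rules is polygon-boundary to
polygon-boundary. A unit with no neighbour is attached to its nearest unit
when within the connection threshold (default 5 km) — implemented as graph-
edge insertion, not polygon redrawing, which is equivalent for the weights
and reversible — and reported as an excluded isolate when beyond the drop
threshold (default 10 km). Aggregation of sparse units is by explicit
mapping (no automatic sample-size threshold), unioning polygons and adding
counts; the merged unit keeps the target's id and name and retains the
source centroids as interpolation anchors.

Weights are binary and symmetric (`w_ij = 1` for neighbours), never
row-standardized; `S0 = Σ w_ij`, `S1 = ½ Σ (w_ij + w_ji)²`,
`S2 = Σ_i (w_i· + w_·i)²`. Voronoi (Thiessen) cells are built by exact
half-plane intersection against the bounding region — O(n²) polygon clips,
robust and exact for the tens of units this tool targets.

## Moran's I

`I = (n/S0) · Σ w_ij z_i z_j / Σ z_i²` on mean-centered values. The
analytic test uses the randomization-assumption variance (Cliff–Ord) with
kurtosis correction `b2 = n Σz⁴/(Σz²)²`; it equals the exact first two
moments of `I` over all `n!` value-to-unit assignments, which the tests
verify by exhaustive enumeration up to n = 7. The default alternative is
one-sided "greater" (positive autocorrelation), two-sided available by
flag. The permutation test reassigns values to units `nsim` times
(default 10 000) and uses `p = (1+m)/(nsim+1)`, so p is never 0 and is
bit-reproducible given a seed. The analytic formula needs n ≥ 4; the
statistic requires non-constant input.

## SAR error model

`y = Xβ + u`, `u = λWu + ε`, `ε ~ N(0, σ²I)`. With `A(λ) = I − λW`,
β and σ² are concentrated out by GLS and λ maximizes

```
LL(λ) = −(n/2)(ln 2πσ̂²(λ) + 1) + Σ_k ln(1 − λ ω_k)
```

with `ω_k` the eigenvalues of the (symmetric) `W`; the eigenvalue route to
the log-determinant is verified against direct determinants. λ is searched
by bounded scalar minimization (Brent) on the feasible interval
`(1/ω_min, 1/ω_max)` shrunk by a relative 1e−6 at the endpoints; a
boundary optimum raises a warning. σ̂² is pure ML (no degrees-of-freedom
correction), matching the likelihood-ratio construction:
`lr_p = χ²₁ tail of 2(LL(λ̂) − LL(0))`, where LL(0) is exactly the OLS
log-likelihood. Covariate p-values are two-sided Wald z-tests with
covariance `σ̂² (XᵀA(λ̂)ᵀA(λ̂)X)⁻¹`. Fitted values include the spatial
signal, `Xβ̂ + λ̂W(y − Xβ̂)` — the natural in-sample predictor for mapping
predicted heterozygosity.

At n ≈ 25–36 units the LR test of λ = 0 is mildly anticonservative
(empirical size ≈ 6% at nominal 5% in the calibration test); this is the
usual small-sample behaviour of ML ratio tests and is why the calibration
test asserts a band around the nominal level rather than equality.

Forward selection starts from the intercept model and greedily adds the
candidate with the smallest Wald p (ties broken by name for determinism),
up to `max_terms` (default 4). Every visited model in which *all*
covariates are individually significant at α (default 0.05) is retained —
deliberately a set of defensible models, not a single winner; removal
steps are not performed (pure forward). The influence of an extra
covariate on a retained model "improves" it only if the extra term is
significant and all existing terms stay significant.

## Landscapes and divergence

Point layers anchor each unit's value at its centroid; units aggregated
from several postal areas (or otherwise carrying sub-centroids) contribute
one point per sub-centroid, all with the unit's single value — this
smooths the surface over their extent and avoids single-anchor artifacts
for disproportionately large units.

The interpolator is the regularized spline with tension:
`z(p) = a₁ + Σ_j c_j R(r_j)`, `R(r) = −[ln ρ + E₁(ρ) + γ]`,
`ρ = (φ r/2)²`, with `R(0) = 0` by continuity. Coefficients solve the
bordered dense system with the side condition `Σ c_j = 0`; the smoothing
parameter adds to the diagonal (0 = exact interpolation, which the tests
verify to 1e−6 and against an independently coded dense solve). The
tension parameter is expressed per map extent (the larger side of the
point bounding box), so the default (40) is scale-free; smoothing defaults
to 0.1. The default raster is 200 square cells across the study bounding
box. Surfaces can be clipped to the study polygon; outside cells are
nodata (NaN) and excluded from all extremes and summaries. Rasters are
written as ESRI ASCII grids (rows north to south).

The divergence landscape is `|observed − predicted| / max_rg × 100` per
cell, `max_rg = max − min` of the observed landscape over valid cells —
divergences read as percent of the observed range, making models
comparable. Note that `max_rg` comes from the *interpolated* surface, not
from the raw per-unit values (the spline may not attain the raw extremes,
and replicated anchors shift them slightly). Models are ranked by
ascending mean divergence with sd as tie-break.

## Synthetic data

The generator emulates the study conditions: 13 land units with the
published per-unit sample sizes (728 subjects), 212 SNPs with native
minor-allele frequencies uniform in [0.10, 0.50], HWE genotypes, an
east-west gradient in the per-unit immigrant fraction (default range
0–40%), an immigrant allele-frequency shift `delta` (default +0.10,
bounded so frequencies stay in (0,1)), a major-immigrant share of 0.80
among immigrants, and per-unit mean-age/education fields drawn from a SAR
process with λ = 0.15. Immigrant genotypes come from a single
shifted-frequency pool rather than a coalescent model — sufficient to
create the heterozygosity contrasts the framework detects, and transparent
for expected-value checks (`E[H_O] = 100·mean_k 2q_k(1−q_k)`). The
reference fixture's geometry is a schematic square tiling, not real
administrative boundaries: the pipeline consumes only topology and
centroids, which is exactly what the fixture must reproduce (its per-unit
counts are exact; ages and education values are deterministic fillers
within the study ranges).

What passing tests therefore show: the estimators are correct on data
satisfying the model assumptions (HWE, exchangeable subjects within
pools, SAR residual structure on a known graph). What they do not show:
robustness to linkage disequilibrium between loci, genotyping batch
effects, non-HWE structure within units, or misspecified geometry — real
data can violate all of these.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to give tight Monte-Carlo error
at interactive runtimes: 2000 null replicates at nsim = 199 for the
permutation-test size (the (1+m)/(nsim+1) convention makes the nominal
5% level exactly attainable at nsim = 199), 500 replicates for λ recovery
on a 6×6 rook lattice, 300 for LR-test calibration. Every random stage
takes an explicit seed (numpy `default_rng`); pipeline runs record all
seeds and parameters in `manifest.json` and are byte-reproducible.

## Limitations

* No spatial-lag (autoregressive-response) models, AIC selection or
  cross-validation; no kriging; no local Moran/LISA or Geary's C.
* No survey weighting or imputation of missing socio-demographics.
* Inference at n ≈ 12–13 units is necessarily fragile: Wald p-values and
  the λ LR test rely on asymptotics that are optimistic at that size; the
  divergence-based model comparison is descriptive, not inferential.
* The Voronoi construction is exact but quadratic in the number of units;
  it is not meant for thousands of units.
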