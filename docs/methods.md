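# Methods

## The estimation problem

A stand of plants occupies a rectangular window; its density ρ (stems
per hectare) is the number of stems divided by the area. A PCQM survey
estimates ρ from distances alone: *N* sample points are placed at
random, the plane around each point is divided into four axis-aligned
quadrants, and the distance from the point to the *g*-th nearest stem
in each quadrant is recorded (order *g*: PCQM1/2/3 measure the
1st/2nd/3rd nearest; nearer stems are skipped). Writing R_ij for the
distance at point *i*, quadrant *j*, and k = 4:

* published family: ρ̂ = N·k·(gk − 1) / (π Σ R²) — numerators 12N, 28N,
  44N for g = 1, 2, 3;
* corrected family: ρ̂ = k·(gNk − 1) / (π Σ R²) — numerators 4(4N−1),
  4(8N−1), 4(12N−1).

Under a homogeneous Poisson process of intensity λ, π λ Σ R² is a
Gamma(gNk, 1) variable: each of the gNk measured stems contributes an
independent unit-exponential increment of scaled squared distance. Since
E[1/Gamma(m, 1)] = 1/(m − 1), the unbiased multiplier is gNk − 1 — the
corrected numerator. Using the per-point count gk instead (the
published family) biases the estimate by the factor (gk − 1)/(gk):
−25%, −12.5%, −8.33% for g = 1, 2, 3. The two families coincide at
N = 1, and both are equivariant under rescaling of distances
(ρ̂ → ρ̂/c² when R → cR). Densities are computed in m⁻² and reported per
hectare (× 10⁴); distances are meters throughout.

The implementation accepts any g ≥ 1 through the general formulas, with
g ∈ {1, 2, 3} as the named presets. No finite-sample corrections beyond
the formulas themselves are applied, and no variance or confidence
interval estimator is provided (none is established for PCQM).

## Synthetic stands

Three generators produce populations with an exactly known density —
each returns exactly *n* points, so every realization of a spec has the
same true ρ.

* **Random**: *n* points i.i.d. uniform in the window (binomial
  pattern; the fixed-count analogue of a homogeneous Poisson process).
* **Aggregated**: `round(intensity · n)` points live in clusters, the
  rest are uniform background. Cluster centres are uniform in the
  window; the cluster count is `max(1, round(intensity · n /
  mean_cluster_size))` with `mean_cluster_size = 10` by default, and
  each clustered point is assigned a centre uniformly at random and
  placed uniformly on a disc of `cluster_radius` around it, redrawn
  until inside the window (clipping would pile mass on the boundary).
  The cluster-size distribution is an open modelling choice; the
  defaults produce the Clark–Evans values expected of "10–50% of the
  stand in 1–3 m clumps" scenarios (e.g. R ≈ 0.80 at radius 1 m,
  intensity 50%, 3,000 stems/ha), and `mean_cluster_size` is exposed
  for anyone wanting a different clump geometry.
* **Regular**: simple sequential inhibition — uniform proposals are
  accepted only when at least `repulsion` meters from every accepted
  point, so the hard-core minimum distance is guaranteed by
  construction. Acceptance is checked against a spatial hash grid (cell
  side = repulsion), making each test O(1). After 1,000·n consecutive
  rejections the spec is declared infeasible and a packing-failure
  error reports the attempts made; this terminates impossible requests
  (e.g. 3,000 points at 10 m spacing in 1 ha, where the jamming limit
  is two orders of magnitude lower) deterministically.

Stand structure is summarised by the Clark–Evans aggregation index
R = (mean nearest-neighbour distance) / (0.5/√λ̂), λ̂ = count/area, in
its original uncorrected form (no edge correction). At the densities
these scenarios use (≥ 2,000 stems/ha in 1 ha) the edge term is
negligible and the uncorrected index reproduces the expected values to
two decimals: R ≈ 1.00 random, 0.80 aggregated (1 m / 50%), 1.42
regular (1.0 m repulsion). For sparse patterns in small windows the
uncorrected index is biased upward; that regime is outside the
simulated scenarios.

Windows are closed on all sides; coordinates are continuous doubles.
Only homogeneous, isotropic generators are provided — no inhomogeneous
or anisotropic processes, and no toroidal wrapping.

## The virtual survey

Sample points are i.i.d. uniform on the interior rectangle obtained by
trimming `boundary_fraction` (default 0.10) of each extent from *each*
edge — the central 80% × 80%. This boundary strip keeps quadrant
searches away from the window edge, where distances would be truncated
and densities overestimated. (The alternative reading — 10% total, 5%
per side — would only change the sampled sub-region, not any estimator
arithmetic; the stricter trim was chosen.)

Quadrants are fixed, window-axis-aligned, half-open sectors
counter-clockwise from the +x axis: [0°, 90°) → Q1, [90°, 180°) → Q2,
[180°, 270°) → Q3, [270°, 360°) → Q4. The half-open convention puts a
stem lying exactly on an axis in exactly one quadrant; orientation is
not randomised per point, matching standard compass-quadrant field
practice. The g-th-nearest search is an exact vectorised brute force
over all stems (distance matrix, per-quadrant masking, partial sort);
at the stand sizes PCQM is used on (10³–10⁴ stems) this is faster than
a spatial index and is validated bit-for-bit against an independent
per-stem scan in the test suite. Equidistant stems are resolved by the
partial sort's ordering — a measure-zero event for continuous
coordinates.

Vacant quadrants (fewer than g stems) raise an error by default; a
`redraw` policy replaces such sample points with fresh draws, up to
100·N total draws, for sparse user data. A sample point coinciding
exactly with a stem is always redrawn, keeping Σ R² > 0. Quadrant
vacancy corrections of the PCQM+ protocol (vacant-quadrant weighting,
multi-stemmed plants) are deliberately out of scope, as are angle-order
estimators with k ≠ 4.

## Monte Carlo evaluation

A scenario crosses one stand specification with sample sizes
(default grid 10, 15, 20, 25, 30, 50, 100), orders (1, 2, 3) and both
families, at I = 1,000 replicates per cell (configurable). Each
replicate re-establishes the population from the scenario's parameters,
draws fresh sample points, measures all requested orders at those
points in one pass (as a field crew would), and applies both families
to the same distances. Per-replicate RNG streams derive from (master
seed, scenario id, N, replicate), so any run replays bit-for-bit and
cells are mutually independent.

Re-establishing the stand each replicate is the default because the
alternative — surveying one fixed realization 1,000 times — makes every
cell summary conditional on that realization's idiosyncrasies: the
conditional mean of the corrected estimator wobbles with a standard
deviation of about 2% across realizations (measured over independent
5,000 stems/ha stands), an offset that does not shrink with I and
swamps the Monte Carlo standard error (~0.16%). The unconditional
protocol measures the estimator property of interest; `regenerate:
scenario` is available for studying a particular stand (imported stem
maps are inherently fixed).

Accuracy per cell is summarised by RRMSE = √(Σ(ρ̂ − ρ)²/(I ρ²)) and
RBIAS = (mean ρ̂ − ρ)/ρ (negative = underestimation). RRMSE ≥ |RBIAS|
always holds when both are computed from the same replicates, and the
two families are algebraically linked per cell: RBIAS_pub + 1 =
(RBIAS_corr + 1)·N(gk−1)/(gNk−1), because they divide the same distance
sums. Failed replicates (vacancy on sparse stands, redraw budget
exhausted) are recorded with a status column and excluded from the cell
summary, never imputed; the cell's `n_failed` flags them.

Distributional comparisons use rank tests on the raw per-replicate
estimates: the two-sided Wilcoxon rank-sum test between families, and
the Kruskal–Wallis omnibus across orders followed by Dunn's pairwise
z-test on mean pooled ranks (tie-corrected) with Holm adjustment
(unadjusted p-values are also exposed). Dunn/Holm was chosen because
the downstream use is a significant/not-significant call at α = 0.05;
the tests are run per cell, with pooling across sample sizes left to
the caller. Note that at I = 1,000 even ecologically trivial shifts
reach significance between families; the omnibus across corrected
orders at large N is the interesting null.

### Expected behaviour at study scale

With I = 1,000 on random stands the corrected family is unbiased
(|RBIAS| ≲ 0.01 at N = 100) and its RRMSE tracks the theoretical
1/√(gNk − 2): ≈ 0.13 at N = 15, 0.075 at N = 50, 0.05 at N = 100 for
PCQM1. The published family sits at RBIAS ≈ −0.25/−0.125/−0.085 for
g = 1/2/3 independent of N. Hard-core regularity (repulsion 1.0 m,
3,000 stems/ha) thins out short distances and inflates the corrected
estimate (RBIAS ≈ +0.40 at g = 1, +0.11 at g = 3); strong clustering
(1 m clusters holding 50% of stems) stretches the distances seen from
points outside clumps and deflates it (RBIAS ≈ −0.39 at g = 1). These
are the values the acceptance script recomputes.

## What the synthetic stands do and do not show

The generators emulate idealised homogeneous stands: exact counts,
isotropy, no size structure, no inhomogeneity, no measurement error.
Passing tests therefore demonstrate the estimators' sampling properties
under controlled spatial structure — not robustness to density
gradients, observer error, multi-stemmed plants or species mixtures in
real forests. Real stem maps can be imported as `x,y` CSV (meters) and
surveyed with the same machinery, at which point the "true" density is
the map's own count per area.

## Numerical and interface choices

* Determinism: every public entry point takes a seed (int or numpy
  `SeedSequence`); identical inputs and seed reproduce outputs exactly.
* Problem sizes: the test suite runs the headline scenarios at the full
  I = 1,000 and the structural checks at small n, keeping the default
  suite around two minutes on one CPU.
* CSV round trips are exact: writes use 17 significant digits and reads
  use round-trip float parsing; results CSVs carry 10 significant
  digits.
* Errors are specific (invalid spec, packing failure with attempt
  count, vacant quadrant naming point and quadrant, degenerate sample,
  parse errors with line numbers) and derive from one `PCQMError` base.
* The YAML scenario config is versioned (`version: 1`, documented in
  `pcqm.cli`); logging goes to stderr, data to files/stdout; omitted
  seeds are generated and logged so any run can be replayed.
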