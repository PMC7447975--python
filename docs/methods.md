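# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## The analysis problem

Police collision registries record events, not risk: a falling event count
can hide rising danger if fewer people cycle, and vice versa. The pipeline
therefore (i) builds exposure denominators — how many people cycle and how
far — from weighted household travel surveys; (ii) expresses fatal and
nonfatal collision counts as standardized rates against those denominators
and tests their change over time; (iii) locates where fatal collisions
concentrate in space; and (iv) models which factors make an individual
collision fatal.

## Exposure estimation

**Population.** Survey person records carry design (expansion) weights; the
bicyclist population in a zone–year–stratum cell is the Horvitz–Thompson
sum of weights of bicyclist records in the cell. The estimator is unbiased
under any single-inclusion design and is invariant to record order and to
splitting a weight *w* into *w/2 + w/2* (both are tested).

**VKmT.** Weighted OD trips are routed between zone centroids snapped to
their nearest network nodes, minimizing edge length. Among equal-length
routes the lexicographically smallest node sequence is chosen, which makes
routing deterministic and testable against brute-force enumeration. Each
route is intersected with the zone polygons; zones claim route segments in
lexicographic zone-id order, so segments lying exactly on a shared boundary
are counted once and the per-zone lengths partition the route exactly
(conservation is asserted to float precision). OD ends are zone centroids
only — no within-zone randomization — matching how such surveys report
trips.

**Interpolation.** Surveys exist at irregular years (default 2005, 2011,
2014, 2015, 2017). Each stratum series is linearly interpolated between
adjacent survey years and linearly extrapolated beyond the observed range
from the two nearest surveys. Extrapolated values are clipped at zero:
populations and distances cannot be negative, and a declining small stratum
can otherwise extrapolate below it. Provenance (observed / interpolated /
extrapolated) is kept per cell.

**Validation errors.** Two figures of merit: the total percent error
`100·|Σa − Σe|/Σa`, and the unweighted mean of per-group absolute percent
errors over a stratification. Groups with a zero actual value have no
defined percent error; they are excluded and counted. Per-group errors are
only meaningful for groups large enough that sampling discreteness does not
dominate, so the acceptance script reports the stratified error over
sex × age groups rather than per-zone cells.

## Standardized rates and SMR

Monthly rates are directly age-standardized with WHO World Standard
Population 2000–2025 weights, renormalized over the age groups with
positive denominators in the month (this preserves the identity that a
common stratum rate *r* standardizes to *r*). Denominators are the
interpolated bicyclist population, or daily VKmT × days in month; scales
are per 100,000 persons and per 100 million VKmT. A positive count over a
zero denominator is flagged undefined, never silently zeroed, and flagged
months are excluded (and counted) from yearly means.

Yearly summaries use the t distribution with df = months − 1 on the 12
monthly rates; t rather than normal quantiles because 12 observations per
year is small. Between-year change is `100·(mean_a − mean_b)/mean_a` with a
Welch two-sample t-test on the monthly rates; the sex difference in change
is the year × sex interaction of a two-way linear model on the 48
sex-by-month rates. Both tests hold their nominal type-I error in null
simulations (tested).

The SMR is observed monthly deaths over expected deaths,
`E = Σ_a rate_ref(a)·pop(a)`, per sex and combined. The reference defaults
to the internal pooled all-years rates — against which total observed
equals total expected by construction (tested) — and accepts any external
age × sex monthly-rate table.

## Hotspot detection

All coordinates must be planar metres; nothing in the package transforms
geographic coordinates.

**Ripley's K** is computed as
`K̂(r) = |W|²/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r)/A_ij` with the translation
correction `A_ij = (W_x−|dx|)(W_y−|dy|)` for rectangular windows (reduces
to the uncorrected estimator when `A_ij = |W|`). The CSR reference is πr²;
clustering is declared where K̂ exceeds the upper pointwise envelope of
seeded uniform simulations.

**Kernel surface.** The density is a homoscedastic Gaussian mixture centred
on the events, evaluated on a raster by the separable product of 1-D
kernels (verified against naive per-cell summation to 1e-12). The bandwidth
maximizes the leave-one-out log-likelihood `Σᵢ log f₋ᵢ(xᵢ)` over a
log-spaced candidate grid (default 10 m – 5 km) with one golden-section
refinement. The lower bound matters: with coincident points the LOO
likelihood diverges as σ → 0, and the bound turns that degeneracy into a
boundary solution.

**Grid size from the 95% contour.** The highest-density region threshold is
the largest density t such that cells with f ≥ t hold 95% of the raster
mass; components are 4-connected. The quadrat side is the square root of
the smallest component's area — the kernel's own significant-cluster
scale — capped at the side of a square whose area equals a single kernel's
95% HDR disk (radius σ√(2 ln 20)): without the cap, a single merged
component on a large window collapses the grid to a handful of quadrats.
Both σ and the side are overridable.

**Quadrat test.** Quadrats are half-open `[x0,x1)×[y0,y1)` (last
row/column closed), so counts partition the events; clipped edge quadrats
keep their true area and expectations are area-weighted. The statistic is
the index of dispersion `X² = Σ(nᵢ−Eᵢ)²/Eᵢ`, df = #quadrats − 1, upper χ²
tail. The top-5% rule flags quadrats at or above the 95th rate percentile,
ties included; a fully tied grid flags everything and raises a uniformity
warning rather than pretending to discriminate.

## Severity GAMM

The fatality probability model is
`logit P(fatal) = β₀ + Xβ + Σ_k f_k(z_k) + f_xy(x,y) + b_zone + b_year:zone`
with binomial likelihood. Implementation choices:

- **Bases.** 1-D smooths are cubic P-splines: k (default 10) B-spline basis
  functions on uniform extended knots with a second-order difference
  penalty. Uniform (unclamped) knots are deliberate: the penalty null space
  then maps to curves exactly linear in the covariate, so as λ → ∞ each
  smooth provably collapses to a line (tested against a parametric
  logistic fit). Time of day uses a cyclic P-spline with period 24 h, since
  the night-time excess spans midnight. The 2-D spatial term is a low-rank
  thin-plate-type radial basis (r² log r on a knot grid, default rank 30)
  with its kernel matrix as penalty, eigenvalue-clipped to PSD, and the
  linear null space unpenalized. Every smooth carries a sum-to-zero
  constraint absorbed by reparameterization.
- **Random intercepts** are ridge-penalized group dummies; with the
  binomial scale fixed at 1, a penalty λ corresponds to a Gaussian random
  effect with SD 1/√λ, which is how the reported random-effect SDs are
  obtained.
- **Fitting.** Penalized IRLS with step-halving (tolerance 1e-8 on the
  penalized deviance); smoothing/variance parameters maximize the Laplace
  approximation to the restricted marginal likelihood,
  `ℓ_p(β̂) + ½log|S_λ|₊ − ½log|H+S_λ|`, by bounded scalar search (one
  penalty) or Nelder–Mead (several), warm-starting β between evaluations.
  A cross-check against mgcv's REML fit on shared data agrees on a linear
  coefficient to 0.02 and on its SE to 1% (tested).
- **Inference.** SEs come from the Bayesian posterior covariance
  (H + S_λ)⁻¹; linear terms get Wald z-tests and conventional star levels.
  Smooths are reported as centred log-odds contributions on a covariate
  grid with 95% bands.
- **Separation.** A level with one outcome class drives its coefficient to
  ±∞; coefficients drifting beyond |15| log-odds are frozen and flagged
  `separation` instead of being reported with absurd SEs.
- **Screening.** Bivariate p < 0.2 (χ² for categoricals, Welch t for
  continuous — the specific tests are a package choice), missingness < 10%,
  and pairwise |r| ≥ 0.8 drops the member with more missingness. Every
  exclusion is logged with its failing rule.
- **Oversampling.** The minority fatal class is resampled with replacement
  to the smallest count reaching the 30% target (exact when counts divide).
  Oversampling shifts the intercept (case-control style) but leaves slopes
  consistent (tested); reported SEs on the balanced fit are optimistic
  because duplicated rows overstate information, so planted-effect recovery
  is always assessed on raw-data fits.
- **Thresholds.** The covariate values where a smooth's 95% band crosses
  zero are found by linear interpolation on the evaluation grid. Because
  smooths are centred, the flat region of a hinge-shaped effect sits at
  −mean(effect); the significance onset lands near the kink only when the
  effect lives in a small upper tail of the covariate distribution, which
  is exactly the regime of terrain-slope effects in a mostly-flat city.

## The synthetic city

The generator defines the package's study conditions; its defaults are
fixed, not tuned per experiment:

- ~100 Voronoi zones (grid optional) on a 20 km window; a jittered lattice
  road network whose jitter keeps edge lengths generically unique (no
  shortest-path ties); edge attributes (lanes, lane width, speed limit,
  bike path, transit route) feed the traffic-stress rating.
- Five surveys (2005, 2011, 2014, 2015, 2017) with Poisson sampling: each
  population unit is sampled with probability π = n/N and weight 1/π, so
  expansion is unbiased with known variance N/π (used as the oracle in
  tests). The bicyclist population triples between 2011 and 2017 by
  default; collisions grow 40% over the same period, so rates per bicyclist
  fall by roughly half — the joint condition the rate-trend analysis is
  designed to detect.
- Zone residence and attraction shares are heavy-tailed (Dirichlet 1.0 and
  0.6): near-uniform trip ends would make the exposure field far flatter
  than any real city, inflating the cross-validated kernel bandwidth and
  coarsening the quadrat grid until it has fewer top-5% cells than planted
  hotspots.
- Collisions are placed by drawing an OD flow proportional to its VKmT and
  a point uniform along its shortest path, plus 30 m Gaussian jitter
  (geocoding noise); `placement="uniform"` provides the spatial null for
  calibration tests, since path-constrained points are intrinsically
  non-CSR. The marginal fatality fraction is calibrated to 358/9950 ≈ 3.6%
  by an intercept offset that leaves all planted slopes untouched (and is
  ~0 when all effects are null). Hotspot centres are sampled from the
  exposure process itself and multiply the fatality odds (default ×8)
  within their radius — a hotspot where nobody rides would be undetectable
  by construction.
- Terrain slope is a smooth field, mostly flat with a hilly quadrant
  (right-skewed, ~0.5–12%); time of day is a day/night circular mixture;
  the counterpart-vehicle mix, with planted log-odds (cargo +2.0,
  motorcycle −0.8, bus +1.0), mirrors the magnitudes such registries show.

**What passing tests show — and don't.** Synthetic validation establishes
that each estimator recovers what its own generative model planted, at
realistic sample sizes and class imbalance, and that the test statistics
hold their nominal levels under their nulls. It does not establish
robustness to what the generator omits: under-reporting and duplicate
records across sources, geocoding failures worse than Gaussian jitter,
survey nonresponse and weight miscalibration, within-zone OD dispersion,
congestion-dependent route choice, or secular covariate drift. Results on
real registries inherit those caveats.

## Problem sizes

Defaults used by the test suite and the acceptance script: 16–49-zone
cities for unit and recovery tests, 100 zones at 20 km for the end-to-end
study; ~9,950 collisions per draw; 50 seeds for recovery studies; 500
replicates for type-I-error calibration and 199 simulations for CSR
envelopes. These sizes give the Monte-Carlo bands quoted in the tests
(e.g. ±3 binomial SE) while keeping a full run in minutes on one CPU.
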