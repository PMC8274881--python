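# Methods

This note documents the statistical models behind `lithospat`, the
parameters that matter, the numerical choices, what the synthetic
generators do and do not emulate, and the places where the design was
genuinely open.

## Windows, patterns, distances

The observation window is a simple polygon in local planar metres; there
is no CRS handling because site grids are local, and the analysis is
strictly 2-D (elevation travels as an inert mark). Containment is *closed*
— a point on the boundary belongs to the window — because plotted finds on
a trench edge are part of the assemblage. Duplicate coordinates are legal:
two artifacts can share one total-station reading.

Nearest-neighbour structures are exact Euclidean k-NN queries (scipy
cKDTree) with distance ties broken by lowest point index, so every
Monte-Carlo rerun is bit-reproducible.

## Intensity estimation

λ̂(u) = Σᵢ κ_h(u−xᵢ) / c_h(u), with κ_h the isotropic Gaussian density of
standard deviation h metres and the *uniform* edge correction
c_h(u) = ∫_W κ_h(u−v)dv. Pixel values are exact kernel sums over the data
(no binning), so they agree with a brute-force oracle to 1e-10; the edge
correction is a discrete Gaussian blur of the window mask, and all window
integrals in the package use one quadrature rule — sum over in-window pixel
centres × pixel area. With the correction on, ∫λ̂ ≈ n within pixelisation
error (< 2% at pixel ≤ h/4) and a homogeneous pattern shows no systematic
depression near the boundary (measured boundary/interior ratio 1.01).
Default mapping resolution is window diameter / 128; the Diggle correction
and adaptive bandwidths are out of scope.

Bandwidth selection:

* **Likelihood CV** (the default): maximise
  LCV(h) = Σᵢ log λ̂₋ᵢ(xᵢ; h) − ∫_W λ̂(u; h)du, the leave-one-out Poisson
  likelihood. The search grid is 24 log-spaced values in
  [diameter/100, diameter/4]; the CV integral uses a diameter/64 grid —
  the search only ranks candidates, so it needs less resolution than the
  final map. If every candidate gives a zero leave-one-out density at some
  point the selection fails loudly, advising a wider grid.
* **Cronie–van Lieshout**: minimise |Σᵢ 1/λ̂_h(xᵢ) − |W||, using the full
  (not leave-one-out) estimate, with +∞ objective where λ̂ vanishes at a
  data point.

When a fitted intensity is later used as a divisor (G-function weights),
map values at data points are floored at the 1st percentile of positive
in-window values; the clipping is logged.

## CSR tests

* **Quadrat chi-square**: the window is cut into n_tiles vertical slabs of
  exactly equal area (cut abscissae found by root-finding on the
  cumulative-area function — reproducible on any simple polygon, unlike ad
  hoc tile grids). X² = Σ(nⱼ−eⱼ)²/eⱼ against χ²(n_tiles−1). Points exactly
  on a cut fall in the left slab.
* **Hopkins–Skellam**: A = Σ d_P(s)² / Σ d_E(s)², where d_P are distances
  from uniform sample locations to the nearest find and d_E are
  nearest-neighbour distances of randomly chosen finds. Orientation:
  clustering inflates the empty-space distances, so **A > 1 means
  clustered** (the literature is split on which way the ratio is written;
  this is the convention used throughout). The null distribution is built
  by CSR resimulation with the same n (199 draws by default) rather than
  the classical beta approximation, which is biased in irregular windows.
* **Scan test**: for each centre u on the scan grid, with n_in points in
  the clipped circle b(u,r)∩W and e_in = n·area(b∩W)/|W|, the one-sided
  LRT is 2[n_in log(n_in/e_in) + (n−n_in)log((n−n_in)/(n−e_in))] when
  n_in > e_in and 0 otherwise; the statistic is the max over centres and
  the p-value comes from CSR resimulation. Clipped circle areas are exact
  polygon intersections, computed once per (window, radius, grid) and
  reused across replicates. The scan grid defaults to diameter/32 — circle
  clipping is the expensive step, and a finer grid changes the maximum
  negligibly relative to Monte-Carlo noise. Sweeping the radius and
  reporting which radii stay significant estimates the size of a cluster.

All rank p-values use p = (1 + #{null ≥ obs}) / (1 + n_sim), so with 19
simulations attainable p-values are multiples of 1/20 = 0.05 — the
conventional design for relabelling tests, kept as the default.

## Inhomogeneous G-function and envelopes

The van Lieshout estimator

Ĝ(r) = 1 − (1/n_r) Σᵢ Π_{j≠i, ‖xⱼ−xᵢ‖≤r} (1 − λ̄/λ̂(xⱼ)),

with λ̄ the minimum fitted intensity over data points (the standard
choice) and a reduced-sample border correction: the average runs over the
n_r points at least r from the boundary. Under an inhomogeneous Poisson
process the reference curve is 1 − exp(−λ̄πr²). Beyond the largest r with
a nonempty averaging set the estimator is reported as NaN, not
extrapolated. Note the monotonicity of Ĝ in r is guaranteed only while
the averaging set is fixed; the border correction can introduce tiny local
decreases on patterns with many near-boundary points.

Envelopes: one closure computes the statistic for the data and for every
simulated pattern — the procedure is exactly the same on both by
construction. The default null is an inhomogeneous Poisson process driven
by the data's own fitted intensity map (Lewis–Shedler thinning), with 39
simulations, giving pointwise 2/40 = 0.05 two-sided exceedance at any
fixed r. Pointwise bands are reported along with a *global* test: the
maximum absolute deviation from the grand mean curve (simulations **and**
the observed curve — including the observed keeps the ranks exchangeable
and the test exact; excluding it inflates the null rejection rate to ~10%
in our measurements). Whether the original analyses used pointwise or
global assessment is not recoverable; both are provided.

## Multitype analysis

Type probabilities p̂ₖ(u) = λ̂ₖ(u)/Σⱼλ̂ⱼ(u) share one bandwidth across
types (pooled likelihood CV by default); the edge correction cancels in
the ratio. Tolerance contours: the marks are permuted (positions fixed) 19
times, the observed p̂ₖ is ranked pixelwise against the relabelled
surfaces one-sidedly (elevated probability), and pixels with p ≤ α form
the significance mask — its outline is the tolerance contour. The
one-sided orientation matches how such maps are read (regions where a
type is *over*-represented) and is the only orientation for which α = 0.05
is attainable with 19 simulations. Relative risk p̂/(1−p̂) is a derived
view of the same surface.

The segregation statistic is T = ΣᵢΣₖ (p̂ₖ(xᵢ) − p̄ₖ)², evaluated at the
data points with leave-one-out kernel weights (a point must not vote for
its own type). The sources conventionally associated with this test state
no formula; the sum-over-points form is the interpretive choice most
likely to differ from any original run — an integral-over-window variant
would weight empty regions differently. The kernel weight matrix depends
only on the positions, so it is computed once and reused across all
relabelling replicates.

The nearest-neighbour equality function Ê(k) is the fraction of
``from``-type points whose k-th neighbour (non-cumulative) — or whose
first k neighbours on average (cumulative) — carry the target type; k = 1
non-cumulative is the nearest-neighbour type-match proportion. It uses
only the neighbour ordering, never distances or intensities, which is what
makes it robust to extreme inhomogeneity. Envelopes by relabelling; the
permutation-exact expectation (n_b − 1{a=b})/(n−1) is drawn as the
reference.

## Window partition and uniformity regression

The partition cuts the window "through the emptiest zones": the
symmetrised 3-NN graph (K = 3 following the usual recommendation) loses
its longest edges until the requested number of areas remains. Taken
literally, longest-edge deletion is dominated by outliers — isolated
points peel off as spurious one-point "areas" long before the real sparse
corridors break. A component therefore only counts toward the target once
it holds min_area_size points (default max(2, n/20)); leftover chips are
merged into the nearest substantial component. On a realistic three-cluster
site this yields three similarly sized areas; on data with no subdivision
(one tight blob) no threshold qualifies and the partition fails loudly,
advising explicit `fallback_cuts` — polylines that reproduce any manual
subdivision. Edge-length ties break on sorted point indices, making the
partition invariant to point order.

Uniformity: a multinomial logit of area on dummy-coded categorical
attributes (most frequent level as baseline, zero-start Newton, tol 1e-8,
max 200 iterations; statsmodels MNLogit), Wald z per coefficient, odds
ratios relative to the reference area. Perfect separation is flagged and
reported, not hidden. The report's verdict is "uniform" iff no factor
level survives a **Holm** familywise correction across all non-intercept
coefficients of the model set (raw p-values are reported alongside). With
two models of three predictors each there are ~12 Wald tests; flagging on
raw p ≤ 0.05 would break "uniform" on nearly half of all datasets with no
real area effect, making the verdict uninterpretable. Holm keeps the
familywise error at α and costs essentially no power against real
concentrations (an odds-ratio-5 level at n ≈ 1200 has p ~ 1e-10).

## Techno-economic accounting

Cross-tabulations report counts and percentages of the grand total to two
decimals with round-half-up; published tables sometimes truncate instead,
so comparisons should allow ±0.01. The ratio system: FRR = 100·observed
flakes / negative scars; flake-to-core = (plain + broken + retouched
flakes) / handheld cores; retouch-to-flake = retouched / plain whole
flakes — per material and total, with zero denominators reported as
undefined with a reason rather than silently dropped. The reference inputs
carry two documented quirks of their source: the expected-flake total
(771) exceeds the per-material scar sum (726) and is carried explicitly,
and the handheld phonolite core count differs between the inventory (21)
and the core study (20); the core-study subtotals reproduce the published
ratios and are the ones used. The headline missing-flake figure is
100·(1 − observed/expected), rounded to the nearest integer for reporting
with full precision retained; a surplus (observed > expected) is allowed
and flagged.

## Synthetic data

Generators are pure functions of (parameters, seed): homogeneous Poisson
(and a fixed-n binomial variant for conditional Monte-Carlo nulls),
inhomogeneous Poisson by Lewis–Shedler thinning with an enforced intensity
bound, and the Thomas cluster process with a 4σ parent buffer so edge
clusters are not lost. Labelling schemes: i.i.d. with given proportions,
exact permutation of an existing mark column (the relabelling null), and
pointwise draws from nonnegative type surfaces (the segregation
alternative).

The site fixture emulates a 554 m² irregular excavation window holding
1,229 artifacts: locations follow a three-cluster Gaussian mixture (30% /
30% / 20% weight, σ ≈ 1.7–2 m) over a 20% uniform background — cluster
geometry is a parameterised stand-in, since only figures of the real
pattern exist. Marks reproduce the published category × subtype ×
raw-material cells *exactly* (integer cell counts assigned directly;
largest-remainder apportionment where a derived quantity is not integer),
per-core negative-scar totals match the published per-material counts, and
surface condition reproduces the published fresh/abraded/rounded counts
(the 32 items outside the published condition study carry no reading).
Heavy nodular categories are drawn toward the window periphery by
Gumbel-max weighted sampling without replacement (weight e^{−8·affinity}
on the normalised cluster affinity), emulating the strong observed
contrast between heavy peripheral and light cluster-bound material; masses
are lognormal per material with volcanic rocks heavier. What the fixture
does **not** emulate: taphonomy, vertical structure, real cluster
geometry, within-category mass structure — so tests passing on it show the
*statistical machinery* behaves correctly under the stated conditions, not
that any archaeological conclusion transfers.

## Problem sizes and numerical conventions

The test suite and the acceptance script measure operating characteristics
at deliberate scales: type-I error at 500–1000 null replicates with the
conventional 19-simulation relabelling tests (SE ≈ 0.01 on a 5% rate),
closed-form agreement of G over 200 CSR draws, power and recovery over
100 replicates, and the uniformity verdict over 20 relabelled fixtures.
Patterns of 80–150 points are used for replicated simulations and the full
1,229-point fixture for single-shot integration runs. Scan geometries are
precomputed once per configuration. Floating-point conventions: distances
ties by lowest index; percentage rounding half-up to two decimals;
envelope and rank tests never compare beyond the grid they were computed
on.

## Known limitations

* Fixed (non-adaptive) Gaussian kernels only; K/L/pair-correlation
  functions intentionally omitted (nearest-neighbour methods are the
  robust choice under strong inhomogeneity).
* The scan test uses fixed-radius circles; population-adjusted or elliptic
  variants are out of scope.
* The reduced-sample border correction discards information near the
  boundary and can make Ĝ locally non-monotone.
* The KNN partition is a heuristic; for irregular manual subdivisions use
  `fallback_cuts`.
* Multinomial models accept categorical predictors only, matching their
  use here; no regularisation or model selection.
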