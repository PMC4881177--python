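# Methods note

`aedcatch` implements a two-stage spatial decision framework for placing
automated external defibrillators (AEDs): a Bayesian spatial regression
turns sparse zone-level out-of-hospital cardiac arrest (OHCA) counts
into a smooth demand surface, and a multi-criterion two-step floating
catchment area (MC2SFCA) model turns that surface plus the existing
supply network into per-zone accessibility scores and a deployment
ranking. This note records the model, its assumptions, every default
parameter with its rationale, what the synthetic generator does and does
not emulate, the numerical choices, and the limitations.

## 1. Risk model

### Specification

For zone `i = 1..n` with observed OHCA count `y_i` and covariate row
`x_i` (standardized), the zero-inflated Poisson (ZIP) mixture is

```
y_i = 0                                  with probability p
y_i ~ Poisson(λ_i)                       with probability 1 − p
log λ_i = α + Σ_m β_m x_mi + u_i + v_i
```

The random effects follow the BYM convolution: `u` is an intrinsic
conditional autoregression (ICAR) on the zone adjacency graph,

```
u_i | u_{−i} ~ N( mean of neighbours, 1 / (τ_u · d_i) ),   Σ_i u_i = 0,
```

and `v_i ~ N(0, 1/τ_v)` iid. The zero-inflation component absorbs
zones that structurally report no events (e.g. non-residential cells);
`u` captures spatially smooth unmeasured risk; `v` captures
zone-specific overdispersion.

Covariates (all per zone): population density, % population aged 65+,
% housing land, % transportation land, % public-facility land. They are
z-scored (`ddof = 0`) before fitting; the scaler is returned so new
zones can be projected onto the same scale. A constant column
standardizes to zeros with a warning rather than failing.

### Priors

| Parameter | Prior | Rationale |
|---|---|---|
| `α`, each `β_m` | Normal(0, 10²) | weakly informative on the log scale; standardized covariates keep plausible effects well inside ±3 |
| `τ_u`, `τ_v` | Gamma(shape 1, rate 0.01) | mean 100, diffuse; standard conjugate choice for BYM precisions |
| `p` | Beta(1, 1) | uniform; conjugate with the augmented zero indicators |

### Inference

Metropolis-within-Gibbs MCMC with data augmentation:

1. **Structural-zero indicators** (zones with `y_i = 0` only): Gibbs
   draw with probability `p / (p + (1 − p) e^{−λ_i})`.
2. **`p`**: Beta conjugate update given the indicators.
3. **`τ_u`**: Gamma update using the ICAR quadratic form
   `Σ_{(i,j) ∈ edges} (u_i − u_j)²` and rank `n − 1`.
4. **`τ_v`**: Gamma update from `Σ v_i²`.
5. **`α`, each `β_m`**: adaptive random-walk Metropolis, one scalar at a
   time, on the Poisson likelihood restricted to non-structural zones.
6. **`u`**: single-site Metropolis against the ICAR full conditional
   plus the likelihood. Sites are grouped by graph colouring (greedy)
   and each colour class is updated simultaneously with vectorized
   sparse neighbour sums — mathematically identical to sequential
   single-site updates within a class, since no two members are
   adjacent.
7. **`v`**: fully vectorized single-site Metropolis (each `v_i` enters
   only its own likelihood term).

After every sweep `u` is re-centred to sum to zero and the removed mean
is folded into `α`, which fixes the ICAR level non-identifiability
without changing the likelihood.

Step sizes adapt by Robbins–Monro every 50 sweeps during burn-in toward
a 0.375 acceptance rate (between the scalar-optimal ≈0.44 and
multivariate ≈0.234); adaptation stops at burn-in so the retained chain
is a valid Markov chain. The chain is initialized from the non-spatial
EM fit (below), which removes most transient.

**Defaults:** 10,000 iterations, 2,000 burn-in, thinning 4 (2,000
retained draws). On a 20×20 lattice this runs in a few seconds and
recovers the generating coefficients of the synthetic model to
max-absolute-error well under 0.15 (verified in the test suite and the
results script, not asserted here). All randomness flows from one
`numpy.random.default_rng(seed)`, so runs are bit-reproducible.

### Non-spatial EM oracle

`fit_zip_em` fits the ZIP without random effects by
expectation–maximization: E-step responsibilities
`z_i = p / (p + (1 − p) e^{−μ_i})` for zero observations; M-step sets
`p = mean(z)` and solves the z-weighted Poisson regression by Newton
iterations with step-halving. Tolerance 1e-8 on the log-likelihood, cap
500 iterations. It serves as an independent point-estimate cross-check
and the MCMC initializer; the test suite additionally cross-validates it
against `statsmodels.ZeroInflatedPoisson`.

### Risk surface

The demand input to stage 2 is the posterior mean of the *marginal*
expected count, `D_k = E[(1 − p) λ_k]`, averaging the mixture inside the
posterior expectation (draw-wise `(1 − p^{(s)}) λ_k^{(s)}`, then mean).
`posterior_risk(..., include_zero_inflation=False)` returns
`E[λ_k]` instead, for users who regard the structural zeros as a
reporting artefact rather than true absence of risk.

## 2. Accessibility (MC2SFCA)

Distances are Euclidean between zone centroids and site coordinates, in
metres. For supply site `j` with capacity `S_j` and catchment radius
`d0_j`:

```
Step 1:  R_j = S_j / Σ_{k: d_kj ≤ d0_j} D_k · G(d_kj, d0_j)
Step 2:  A_i = Σ_{j: d_ij ≤ d0_j} R_j · G(d_ij, d0_j)
```

Each site uses **its own** radius in both steps — the "multi-criterion"
element: different facility types get different catchments.

* `onsite_aed`: 200 m — the distance a bystander can cover on foot,
  round-trip budgeted, inside a ~4-minute defibrillation window at
  ~100 m/min effective speed.
* `ems_station`: 3,600 m — a 4-minute drive at 900 m/min (54 km/h).
* Capacity defaults to 1 device/vehicle per site.

The default decay is a normalized Gaussian,

```
G(d, d0) = (exp(−(d/d0)²/2) − exp(−1/2)) / (1 − exp(−1/2))   for d ≤ d0,
G = 0 beyond,
```

which is 1 at the site, falls smoothly, and reaches exactly 0 at the
catchment boundary, so `G` is continuous everywhere. `binary` decay
(`1{d ≤ d0}`) is provided for comparison; it is discontinuous at the
boundary and spreads the ratio uniformly. Boundary convention: `d = d0`
is *inside* the catchment (weight 0 under Gaussian decay, 1 under
binary).

A site whose catchment contains zero total weighted demand gets
`R_j = 0` and is reported in `zero_catchment_sites` rather than raising
— an AED in an empty field is wasted, not an error. Conservation holds
by construction: `Σ_i D_i A_i = Σ_j S_j` over sites with non-empty
catchments (exact under both decay kinds); the test suite checks this
identity to 1e-9 on random instances, alongside a brute-force
double-loop oracle implementation that must agree to 1e-12.

## 3. Priority ranking

Zones with `A_i ≤ threshold` (default 0, i.e. literally unreachable by
any device) are eligible. They are sorted by:

1. **Stratum**: zones farther than 4 minutes from the nearest hospital
   (straight-line distance at 900 m/min) rank before zones within
   4 minutes — a shock from a responding ambulance or quick hospital
   arrival partially substitutes for a public AED near a hospital.
2. **Population**, descending, within each stratum.
3. **Zone id**, ascending, as a deterministic tie-break.

Ranks are contiguous from 1. An empty eligible set returns an empty
list with a warning (a fully served city is a success, not an error).
The speed (900 m/min) and time threshold (4 min) are module constants
and CLI options; 4 minutes is the usual survival-curve knee for
defibrillation delay.

## 4. Diagnostics

Residuals are `y_i − D_i` (observed minus posterior-mean risk). Spatial
autocorrelation is tested with Moran's I under row-standardized
contiguity weights,

```
I = (n / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²,   z = values − mean,
```

with `E[I] = −1/(n − 1)` and a two-sided permutation p-value using
add-one smoothing, `p = (#{|I*| ≥ |I|} + 1) / (n_perm + 1)` (999
permutations by default, seeded). A residual I near its null mean
indicates the BYM effects absorbed the spatial structure. Constant
input raises, since I is undefined. The implementation is validated in
the tests against a literal double-sum oracle and the exact 2×2
checkerboard value I = −1.

`count_zero_accessibility` counts `A_i ≤ 1e-12` rather than `== 0` to
be robust to floating-point dust from the vectorized matrix products.

## 5. Synthetic-city generator

Real OHCA registries are restricted, so the package generates cities
that emulate the *assumed data structure* of a mid-sized Asian city:

* `nx × ny` square zones of `cell_size` metres (default 500 m, the
  granularity of small census statistical areas);
* population density with a monocentric exponential gradient,
  `center_density · exp(−decay · distance)` times lognormal noise
  (defaults 20,000 /km² peak, decay 3e-4 /m, noise sd 0.3 on the log
  scale — a dense core falling to suburban levels ~10 km out);
* elderly share from Beta(2, 14) (mean ≈ 12.5%, right-skewed, matching
  typical zone-level variation around an aging-city mean);
* land-use mix from Dirichlet(3, 1, 1, 5) over
  (housing, transportation, public, other), making housing the dominant
  named use as in residential zones;
* counts from the exact ZIP-BYM generative model above, with ICAR draws
  obtained by Cholesky factorization of `τ_u (D − W) + 10⁻⁶ I` and
  re-centred to sum to zero (the jitter makes the intrinsic precision
  invertible; at 1e-6 its effect is below sampling noise);
* default true parameters `α = 0.5`,
  `β = (0.5, −0.3, 0.2, 0, 0.4)`, `p = 0.3`, `τ_u = 4`, `τ_v = 25`:
  positive density/elderly/public effects, a null coefficient so
  recovery tests include a true zero, and spatial variance dominating
  iid variance as BYM fits typically find;
* facilities placed uniformly or population-weighted (without
  replacement across zones, uniform within the chosen polygon),
  mimicking AEDs following foot traffic.

**What it does not emulate:** road-network travel (all distances are
Euclidean), temporal patterns (day/night, seasonality), building-level
placement (mall vs street), population mobility (residential counts
stand in for ambient population), bystander behaviour, and any
correlation between land-use mix and the density gradient beyond what
the shared geometry induces. Synthetic "populations" are continuous
(density × area), not integers.

## 6. Numerical and interface choices

* **Adjacency**: queen contiguity via an STRtree intersection query on
  the zone polygons; islands are attached to their nearest centroid so
  the ICAR graph is connected. A symmetrized k-nearest-neighbour
  alternative exists for point-only data.
* **Outlier screen** (`filter_density_outliers`): drops zones whose
  density exceeds `multiplier × mean(input densities)`, with the mean
  taken once from the input (not recomputed after removals) — a single
  deterministic pass, order-independent.
* **Accessibility** is computed from the full `(n_zones × n_sites)`
  distance matrix; at census-zone scales (`n ≤ 10⁴`) this is well
  within memory and far faster than spatial indexing.
* **Determinism**: every stochastic routine takes a seed and builds a
  fresh `default_rng`; the CLI derives per-stage seeds by fixed offsets
  from the one user seed, so stage-wise runs and `run-all` produce
  byte-identical outputs. Output files carry a `# config_hash` header
  computed from the scientific parameters only (never the output path).
* **Config**: YAML, flat keys or one level of sections; command-line
  flags override file values.
* Open interface choices resolved in this implementation: distances are
  metres in a projected plane (inputs are assumed already projected);
  GeoJSON and CSV are both accepted for zones; results join back to
  GeoJSON by `zone_id`.

## 7. Limitations

* Euclidean distance understates true travel time in gridded or
  river-cut street networks; catchment radii partially compensate but
  the ranking near the 4-minute hospital boundary is sensitive to it.
* The ICAR prior smooths aggressively where data are sparse; isolated
  high-risk zones can be shrunk toward their neighbours.
* The ZIP structural-zero probability is global (`p` does not depend on
  covariates); zones whose emptiness is predictable from land use are
  handled only through the Poisson mean.
* MC2SFCA conservation means accessibility is *relative*: adding supply
  anywhere changes ratios everywhere; scores should be compared within
  one supply scenario, not across cities.
* The ranking treats population as the sole within-stratum criterion;
  risk-weighted ranking is a one-line change (`D_i` in place of
  population) but is not the default.
* Posterior summaries use the marginal mean only; planners wanting
  exceedance probabilities can compute them from the returned draws.
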