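# Methods

This note documents the models implemented in `greenaccess`, the defaults and
why they were chosen, what the synthetic-city generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Travel-time model

The road network is a planar graph (projected coordinates in meters; the
package does no geodesy — reprojection is input preparation).  Each edge
carries one of nine road classes; each mode is allowed on a class subset at a
fixed speed (km/h):

| class | public transport | cycling | walking |
|---|---|---|---|
| highway | 50 | — | — |
| city_circle | 40 | — | — |
| auxiliary_road | 30 | — | — |
| main_street | 30 | 15 | 5 |
| minor_street | 30 | 15 | 5 |
| ramp | 20 | — | — |
| feeder | 20 | 15 | 5 |
| internal_road | 20 | 15 | 5 |
| subway | 50 | — | — |

"—" means the class is removed from that mode's subgraph, so locations joined
only by such roads are mutually unreachable (infinite minutes).  Edge weight
is `length_m / 1000 / speed * 60` minutes; shortest paths by Dijkstra.
Assumptions worth knowing:

- **Public transport is a speed model, not a schedule model.**  No headways,
  waiting or transfers; an optional constant boarding penalty (default 0 min)
  is available.  This matches the cost structure of planning-stage
  accessibility work, not of GTFS-based routing.
- **Access legs are free.**  Points snap to the nearest node (ties to the
  smaller node id, for determinism) and the snap leg costs zero minutes;
  points farther than the snap tolerance (default 500 m) are flagged
  unreachable rather than silently included.
- Edges are bidirectional unless an explicit `oneway` flag says otherwise.

## Multi-mode 2SFCA

Catchment membership is inclusive (`time ≤ threshold`).  Step 1 computes the
supply–demand ratio of each green space with a *mode-matched* denominator:
each mode's catchment contributes that mode's population.  Step 2 is
evaluated in mode-share form, `A_i = Σ_v (P_iv/P_i)·Σ_{j∈catch_v(i)} V_j`,
which is algebraically the population-weighted quotient but reduces
bit-exactly to the classic single-mode 2SFCA when all population sits on one
mode — that makes oracle comparisons meaningful at zero tolerance.  The
catchment demand and ratio sums are deliberately plain sequential loops in
sorted-id order (problem sizes here are hundreds, not millions), for the same
reason.

Conventions and edge cases:

- Travel time to a multi-entrance green space is the minimum over entrances.
  Belt-shaped parks are represented as several records whose areas partition
  the original area.
- A green space no population can reach gets `V_j = 0` and a zero-demand
  flag (synthetic scenarios legitimately produce them); it is excluded from
  the conservation identity `Σ_i P_i·A_i = Σ_j S_j`, which otherwise holds
  whenever travel times are symmetric (undirected network).
- Communities with zero total population are excluded with a warning.
- Per-mode accessibility columns place the community's entire population on
  that mode (so they equal the plain reachable-ratio sum); the integrated
  column uses the actual mode split.
- Level stratification recomputes both steps on each level's subset; because
  `V_j` depends only on green space *j*'s own catchment, the level columns
  sum exactly to the all-levels result.
- Communities below 12 m²/person integrated access are flagged (strict `<`),
  the garden-city per-capita standard.

**Thresholds from trip surveys.**  "The inflection point of the cumulative
trip-frequency curve" is operationalized as the breakpoint of a continuous
two-segment piecewise-linear least-squares fit, searched over interior
integer minutes; ties prefer the smaller breakpoint, and a breakpoint landing
on the search boundary triggers a warning (no interior slope change).  This
is deterministic and recovers planted breakpoints exactly on noiseless
curves; defaults are 18/23/33 min for walking/cycling/public transport.

## KRLS

Covariates and response are standardized (sample sd; a flag in the CLI path
can disable it).  With Gaussian kernel `K_ij = exp(-||x_i-x_j||²/σ²)` and
default bandwidth σ² = D (the number of covariates), the fit is
`c = (K+λI)⁻¹y`.  λ minimizes the exact leave-one-out SSE via the hat-matrix
identity `e_i^loo = (y_i-ŷ_i)/(1-H_ii)`, searched by golden section on
log λ ∈ [1e-6, 1e3] to 1e-4; with an eigendecomposition of K the whole search
costs one O(n³) factorization.  Everything is deterministic.

Pointwise marginal effects use the closed form
`∂ŷ_i/∂x_d = -(2/σ²) Σ_j c_j K_ij (x_id - x_jd)` (standardized space),
rescaled by `sd_y/sd_xd`.  The average effect per covariate is linear in `c`,
so its variance follows from `cov(c) = σ̂²(K+λI)⁻²`; we estimate the residual
variance as `σ̂² = SSE/(n - tr(H))` — the effective-degrees-of-freedom
correction standard for ridge-type smoothers, which is better calibrated than
`SSE/n` when the surface is flexible.  P-values are two-sided normal.
Quantiles (P25/P50/P75) use linear interpolation between closest ranks.
Best-subset selection enumerates all non-empty covariate subsets (≤ 15
candidates), refits each, and picks the lowest LOO SSE; ties prefer smaller
subsets, then lexicographic order.

Caveats: the average-effect test assumes independent residuals.  Accessibility
is a spatial field; when covariates are themselves spatially smooth, spurious
alignment inflates the test's size somewhat above nominal (measured ~4–8%
at the 5% level on null synthetic cities).  No spatial autocorrelation
correction is applied — that is out of scope by design.

## Deprivation tables

For each mode (walking, cycling, public transport, integrated) accessibility
in original m²/person units is the response and SES proportions are
covariates; one table row per (covariate, mode) with Avg/P25/P50/P75 and
stars (* p<0.05, ** p<0.01, *** p<0.001) on the average effect.  Effects are
therefore in m²/person per unit proportion (a 0→1 change in the covariate),
not percentage points; mind the scale when comparing with other work.
Covariates enter jointly by default; `joint=False` (CLI `--marginal`) fits
one at a time.  Joint fitting partials out shared variation but splits credit
when covariate fields are correlated; the one-at-a-time mode is the sharper
instrument when a single covariate is of interest (and is what the planted-
truth validation uses, since the generator plants on one covariate).  The
change analysis regresses `ΔA` between two timepoints on `ΔSES` over the
common community set; identical timepoints yield a constant (zero) response,
which is reported as all-zero effects rather than an error.

## Synthetic city

The generator exists because the community/road/green-space datasets this
pipeline targets are typically restricted.  It is the package's test bed and
defines the study conditions for validation:

- **Network**: a grid with occasional diagonals (default 20×20 nodes, 700 m
  spacing ⇒ a ~13 km central urban area), edge classes sampled from a mix
  dominated by the four walkable classes (85%) with a sprinkling of highways,
  ramps, city-circle segments and subway links.  Disconnection of slow modes
  across restricted corridors is intentional and realistic.
- **Communities** (default 200) sit at distinct nodes, with total population
  uniform in [500, 5000] and a Dirichlet(7,2,2) mode split — green-space
  trips are predominantly on foot.
- **SES**: five proportions (older 0.24±0.07, unemployed 0.19±0.15,
  illiterate 0.15±0.06, less educated 0.46±0.15, migrants 0.24±0.20) drawn
  as independent Gaussian random fields (squared-exponential covariance,
  1.4 km range) pushed through a Gaussian copula onto Beta marginals matched
  to those moments by method of moments.  The realized field is
  re-standardized before the copula so sample moments hit the targets
  regardless of the spatial draw.  Deprivation clusters in districts, as in
  real cities; the five fields are mutually independent, which real SES
  dimensions are not.
- **Green spaces** (default 2 city-level of 40–80 ha, 20 district-level of
  4–12 ha, 150 community-level of 0.8–3 ha; supply is community-park
  dominant): placed at nodes sampled with log-weight
  `Σ_cov coupling_cov · z_cov(node)`, where `z_cov` is the standardized
  inverse-distance-weighted SES surface.  Negative coupling starves
  high-covariate districts of supply — deprivation is planted through
  *placement*, never by writing accessibility directly.  `deprived_scenario`
  uses coupling −4 on the less-educated share (strong segregation).  Some
  parks are belts split into 2–3 parts along adjacent nodes with the area
  partitioned exactly; others get a second entrance at a neighbor node.
- **Trip surveys**: durations from a two-rate piecewise-uniform density whose
  cumulative curve changes slope exactly at the planted breakpoint (rate
  ratio 4, support up to 2.2× the breakpoint); a noiseless mode places trips
  on the exact quantile grid.
- **Evolution**: `evolve_scenario` densifies the network toward a target edge
  multiplier using short chords, scales populations, and adds green spaces
  with the same placement mechanism, preserving community ids for
  change-on-change analyses.

Everything is a pure function of the config seed; identical seeds give
byte-identical CSVs.

**What passing tests do and do not show.**  The generator produces gridded
topology, node-anchored communities, independent SES dimensions and
piecewise-uniform trip durations.  Real street networks, dasymetric
populations, correlated deprivation axes and behavioral mode choice are all
richer; recovery of planted signals here validates the *machinery* (routing,
catchment algebra, KRLS inference), not the substantive conclusions one would
draw on any particular real city.

## Numerical conventions

- Catchment sums and ratio sums: sequential loops in sorted-id order, so
  oracle comparisons can demand bit-equality.
- Routing oracle tests use edge lengths (multiples of 18.75 km) for which
  every per-mode minute weight is an exact binary fraction; path sums are
  then associative and Dijkstra-vs-Floyd–Warshall equality is checked at zero
  tolerance.  On arbitrary lengths the two algorithms can differ in the last
  ulp for ≥3-edge paths.
- CSV floats are printed with 10 significant digits; reruns of the pipeline
  are byte-identical, and the manifest (config hash, seed, library versions)
  suffices to reproduce a run.
- Verification problem sizes: 20 cities for the conservation identity, 100
  small instances for the 2SFCA oracle, 50 networks ≤ 60 nodes for routing,
  n = 200 for KRLS recovery, n = 25 for the leave-one-out oracle, 50 seeds
  each for planted-deprivation detection and its null control.

## Known limitations

- No distance decay within catchments (binary membership), no gravity or
  kernel-weighted 2SFCA variants, no green-space quality weighting.
- Public transport ignores schedules, transfers and walk-to-stop legs.
- KRLS inference is iid-based; spatially autocorrelated covariates inflate
  its size (quantified above).  Dense O(n³) algebra caps practical n at a few
  thousand communities.
- Green-space levels are opaque labels {1, 2, 3}; nothing in the code assigns
  them semantics beyond stratified reporting.
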