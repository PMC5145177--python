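# Methods

## Model overview

`reefdrift` implements an offline Lagrangian biophysical dispersal model.
Habitat is a set of reef-pixel centers (≈2 km grain) grouped into islands.
Each release day, a fixed number of virtual larvae starts at every pixel
center at 00:00 and is integrated through a prescribed two-dimensional
horizontal velocity field for the pelagic larval duration (PLD).  At the
end of day PLD — and only then — a particle settles if it lies within the
settlement radius of some pixel center; it is assigned to the nearest
qualifying pixel (ties, within 10⁻⁹ km, to the lowest pixel id) so that
one particle produces exactly one settlement event and counts are
conserved.  Particles that leave the flow domain at any step are absorbed
(`lost_offgrid`, no re-entry); survivors that end outside every settlement
disc are `lost_unsettled`.  Fates partition every cohort exactly.

The model is deliberately physics-only: no larval swimming, mortality,
ontogeny, settlement-competency window or variable PLD.  It estimates
*potential* connectivity — what passive transport alone permits.

## Transport

Advection uses the velocity at the particle position, bilinearly
interpolated in lon/lat (and linearly in time for time-varying gridded
fields; analytic fields are evaluated exactly).  The default integrator is
classical RK4 in degree space with velocities converted by the local
metres-per-degree factors (Δlon = Δx/(π R/180 · cos φ), R = 6371 km);
forward Euler is available for cross-checks.  Positions poleward of
±89.4° (cos φ ≤ 0.01) raise a hard error — the conversion degenerates
there and the intended domains are subtropical.

Sub-grid turbulence is a Gaussian random walk: after each advective step,
independent per-axis increments with standard deviation √(2 K dt) metres
are added (converted to degrees at the post-advection latitude).  K is
scalar, isotropic and constant; the per-axis displacement variance after
time t is therefore 2 K t, which is also the basis of the moment estimator
K̂ = (var x + var y)/(4 t) used for parameter recovery.

Defaults: PLD 45 d, settlement radius 5 km, K = 250 m²/s (a value
consistent with drifter-derived estimates in subtropical island waters),
dt = 3600 s, 50 particles/pixel/day, three replicates averaged, daily
releases 2009-05-02 through 2014-04-10 (1805 days; with 687 pixels this
enumerates to 62,001,750 released particles per replicate).  dt must
divide the PLD exactly.  Halving dt changes K = 0 RK4 endpoints on the
double-gyre test field by ≲10⁻¹¹ degrees, so 3600 s is far inside the
converged regime.

Randomness: one master seed; the stream for (replicate r, cohort c) is
`SeedSequence([seed, r, c])`, so cohorts are order-independent,
parallelizable in principle, and runs are bit-for-bit reproducible.

## Velocity fields

Gridded fields are single-layer (the tracking is 2-D, mirroring the use of
one model layer as the dispersal depth), on regular lon/lat grids with an
optional time axis; land cells are NaN and poison any interpolation stencil
touching them.  Units must be m/s — anything else is a hard error rather
than a silent conversion.  I/O uses classic NetCDF (CF-style `u`, `v`
with a `units` attribute) through xarray's scipy backend, plus a CSV
fallback (`lon,lat,u,v` per snapshot) for tests.  Longitudes are
normalized to [0, 360) everywhere internally because realistic Pacific
domains cross the antimeridian; fields supplied on [-180, 180) are
re-expressed on read.  A grid whose re-expression wraps at 0° is reordered
at the wrap; the empty interval between the two blocks is not flagged as
off-grid (known limitation — antimeridian-crossing domains, the motivating
case, are monotone on [0, 360) and unaffected).

Off-domain queries return NaN; there is no extrapolation.  The tracker
checks domain containment after every step, so "off-grid" means absorbed
at the domain edge; masked land cells are caught when next sampled.  A
particle whose final sub-step lands exactly on a masked cell is still
evaluated for settlement (the synthetic scenarios contain no land).

Analytic fields (uniform, solid-body eddy with Rankine decay outside the
core, Gaussian zonal jet, double gyre) are steady, defined everywhere in
their domain, and serialized as config blocks rather than arrays.  Speeds
above 5 m/s are rejected as misconfiguration.

## Connectivity statistics

The pixel settlement matrix S[i, j] counts settled particles by (source
pixel, receiving pixel); binning to islands sums blocks and preserves the
grand total.  Probability matrices are tagged with their direction:

- *rearward* (receiving-normalized): row r is the origin composition of
  settlers at island r, P[r, i] = S[i, r]/Σ S[·, r].  Rows with ≥1 settler
  sum to exactly 1; the diagonal is the self-recruitment vector.
- *forward* (source-normalized): row s is the destination composition of
  island s's successful particles.

Zero-denominator rows are all-zero and flagged (`zero_rows`), and
zero-settler islands report missing (NaN) self-recruitment and mean
distance — never silent zeros and never propagating NaN into matrices.
Difference matrices require matching direction tags (forward is only
comparable with forward, rearward with rearward).

The source–sink index is (E − I)/(E + I) with export E and import I both
*including* self-recruits; the self term cancels in the numerator, so an
island whose settlers are all local scores exactly 0, and the index spans
−1 (pure sink) to +1 (pure source).  Islands with no flux at all score 0
by convention.

Mean dispersal distance per receiving island follows the product-matrix
construction: the pixel settlement matrix is multiplied elementwise by the
pixel great-circle distance matrix, both are binned by island, and column
sums are divided — a settler-weighted mean of source→sink pixel distances.
Distances are haversine on a sphere of radius 6371 km (the mean radius; a
module constant, overridable, since geodesic-library defaults differ at
the 0.1% level).  Same-island pixel pairs keep their true geodesic
distance; only settlement onto the release pixel itself contributes 0 km.

The settlement time series attributes settlers to their *release* date
(cohort success), pooled over replicates.  Island settlement fractions
divide by all particles released archipelago-wide by default (so island
fractions sum to the overall settlement fraction); a per-island-release
denominator is available as a switch because either reading of "percent
successful arrivals" is defensible.  Seasonal analyses are a post-hoc
calendar-month filter (default May–June, the peak spawning season) on the
release dates of one particle set, not a separate simulation.

The Mantel test correlates the off-diagonal cells of two same-shape
matrices (the diagonal is excluded by default because self-recruitment
dominates connectivity matrices; an include-diagonal switch exists) and
builds its null by simultaneous random row/column relabeling of the second
matrix, with one-sided p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1), default
999 permutations.  Constant matrices make r undefined; the result is then
(NaN, NaN) rather than an exception.  Under independent random matrices
the p-values are calibrated (uniform; checked by simulation in the test
suite).

## Synthetic scenarios

The generator emulates a linear island chain — the statistical skeleton of
an archipelago — with configurable island count, pixels per island
(compact ~2 km sub-grids) and spacing along a great-circle bearing, or at
constant latitude when a zonal conveyor must map centers exactly onto one
another.

- **conveyor**: uniform zonal current whose speed is computed from the
  inter-island longitude spacing so K = 0 endpoints land on downstream
  pixel centers to within metres; the 5 km settlement radius absorbs the
  residual spherical-curvature offset.  Expected island matrix: pure
  superdiagonal with count = particles × pixels × release days.
- **broken_chain**: one spacing widened (default 3×) beyond the transport
  range; expected zero flux across the gap — an engineered connectivity
  break.
- **isolated_atoll**: a chain plus one island separated (default 2000 km)
  by more than 10× the 45-day advective + 3σ diffusive range in still
  water; any settler there must be a self-recruit (SR = 1, index = 0).
  Construction fails loudly if the separation does not guarantee
  unreachability.
- **diffusion_only**: still water with configurable K, for variance checks
  and parameter recovery.

A brute-force oracle integrates each pixel's single deterministic (K = 0)
trajectory with an independent 60 s forward-Euler scheme and applies the
same settlement rule; tracker and oracle island matrices agree *exactly*
on all deterministic scenarios because settlement endpoints sit far from
decision boundaries relative to both schemes' numerical error.

What the synthetic scenarios do not emulate: realistic bathymetry and
coastlines, temporally varying mesoscale circulation, spatially variable
diffusivity, habitat-patch size heterogeneity.  Passing tests therefore
demonstrate the correctness of the transport numerics and the statistics,
not the realism of any particular ocean state; conclusions about a real
archipelago require real current fields and habitat through the same
interfaces.

## Problem sizes

Simulation sizes in the tests and acceptance script are chosen so each
scenario still forces its expected outcome with margin: conveyor/broken
chain use 3–4 islands at 20/pixel/day for one release day; the isolated
atoll uses 100/pixel/day over 21 pixels (expected ≳10 settlers at the
isolated island; the probability of zero settlers is ~10⁻⁶); diffusivity
recovery uses 10,000 particles for 2 days (moment-estimator relative
error ≈ 1/√n ≈ 1%, against a 5% band); Mantel calibration uses 200
replicates of 10×10 matrices at 999 permutations.  The full five-year,
687-pixel schedule is enumerated arithmetically, not instantiated.

## Known limitations

- 2-D, single-layer transport; no vertical structure or behavior.
- Settlement only at the final PLD day, not over a competency window.
- Absorbing domain boundaries; no coastline reflection.
- Prime-meridian wrap handling as noted above.
- The Mantel variant (off-diagonal Pearson, joint relabeling) is one of
  several in use; the diagonal-inclusion switch changes r noticeably when
  self-recruitment is strong, so report which variant is used.
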