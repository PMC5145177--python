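# reefdrift

Lagrangian larval-dispersal simulation and marine-connectivity statistics
for island archipelagos.

Coral-reef populations are connected by the pelagic larval stage: spawned
propagules drift with ocean currents for weeks before settling back onto
reef habitat.  `reefdrift` estimates this *potential connectivity* with a
purely physical biophysical model: virtual larvae are released daily from
every habitat pixel, advected through a two-dimensional velocity field
(gridded circulation-model output or analytic synthetic currents), spread
by an eddy-diffusivity random walk, and scored as settled if they end their
pelagic larval duration (PLD) within a settlement radius of a habitat pixel
center.  The package is aimed at marine ecologists and seascape-genetics
researchers who need connectivity matrices, self-recruitment and
source–sink diagnostics from current fields — or who want a fully
synthetic, reproducible testbed for such analyses.

## Model

Particle positions **x** = (λ, φ) evolve per step dt as

    x(t + dt) = x(t) + ∫ u(x, t) dt  +  ξ,     ξ_x, ξ_y ~ N(0, 2K·dt)

with the deterministic advection integrated by classical RK4 over the
bilinearly interpolated velocity field **u** (m/s) and the random-walk
increments ξ (metres, converted to degrees at the local latitude)
parameterizing unresolved turbulence with a scalar eddy diffusivity K.
Defaults describe a generic broadcast-spawning reef fish: PLD = 45 d,
settlement radius 5 km, K = 250 m²/s, 50 particles/pixel/day, three
replicate runs averaged.

From the settlement counts S_ij (released at source site *i*, settled at
receiving site *j*, binned from pixels to islands) the package derives:

- **rearward probability matrix** P_ij = S_ij / Σ_i S_ij — origin
  composition of each receiving island's settlers (rows sum to 1);
- **forward probability matrix** — destination composition per source;
- **self-recruitment** SR_j = S_jj / Σ_i S_ij;
- **source–sink index** (E − I)/(E + I) per island, in [−1, 1];
- settler dispersal-distance summaries via the S∘D product matrix
  (D = haversine great-circle distances, R = 6371 km);
- settlement time series, seasonal (e.g. May–June) subsets, difference
  matrices, and permutation Mantel comparisons between matrices.

Synthetic scenarios with closed-form expected connectivity (conveyor
chain, broken chain, isolated atoll, pure diffusion) plus a dense-step
brute-force oracle make the whole pipeline testable without any
oceanographic download.

## Worked example

`examples/conveyor_connectivity.py` builds a four-island chain with a
uniform current tuned to carry particles exactly one island spacing in 45
days (K = 0) and runs the tracker:

```
island settlement matrix S[source, receiving]:
[[ 0. 20.  0.  0.]
 [ 0.  0. 20.  0.]
 [ 0.  0.  0. 20.]
 [ 0.  0.  0.  0.]]

rearward probabilities (row = receiving island's origin mix):
[[0. 0. 0. 0.]
 [1. 0. 0. 0.]
 [0. 1. 0. 0.]
 [0. 0. 1. 0.]]

self-recruitment per island: [nan  0.  0.  0.]
source-sink index per island: [ 1.  0.  0. -1.]
```

All 20 particles released at each island settle on the next island
downstream: rearward rows of receiving islands are unit vectors pointing
at the upstream source, the head of the chain is a pure source (+1), the
tail a pure sink (−1), and the island receiving nothing has undefined
self-recruitment (reported missing, not 0).  The other examples cover
isolation (`isolated_atoll.py`), eddy-diffusivity recovery
(`diffusion_recovery.py`, prints K̂ = 249.7 m²/s from 10,000 still-water
trajectories) and seasonal matrix comparison (`seasonal_comparison.py`).

A thin CLI wraps the same library calls:

```bash
reefdrift scenario --name conveyor --out run/
reefdrift simulate --config run/config.yaml
reefdrift connectivity --events run/events.csv --habitat run/habitat.csv --out run/stats
reefdrift compare run/stats/rearward_probability.csv run/stats/rearward_probability.csv
```

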