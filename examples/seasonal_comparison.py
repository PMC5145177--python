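"""Seasonal subsetting and Mantel comparison of connectivity matrices.

Runs a three-island chain through a gentle downstream current (one island
spacing per 45-day larval duration) with the default 250 m^2/s eddy
diffusivity over a May-August daily release schedule, then computes the
rearward probability matrix for year-round releases and for the May-June
subset of the *same* particle set (seasonal analyses are a post-hoc filter,
not a separate simulation).  Prints the difference matrix and the
permutation-Mantel correlation between the two.
"""

import numpy as np

from reefdrift import (
    Domain,
    ReleaseSchedule,
    RunParams,
    bin_by_island,
    filter_by_release_months,
    make_analytic_flow,
    make_archipelago,
    mantel_test,
    matrix_difference,
    rearward_probability,
    run_experiment,
    settlement_matrix,
)
from reefdrift.habitat import METERS_PER_DEGREE
from reefdrift.tracker import SECONDS_PER_DAY

spacing_km, lat0 = 60.0, 20.0
grid = make_archipelago(3, 9, spacing_km, origin=(200.0, lat0), constant_latitude=True)
u0 = spacing_km * 1000.0 / (45 * SECONDS_PER_DAY)  # one spacing per PLD
domain = Domain(196.0, 208.0, 16.0, 24.0)
flow = make_analytic_flow("uniform", {"u0": u0, "v0": 0.0}, domain)
schedule = ReleaseSchedule.daily("2009-05-02", "2009-08-31")
params = RunParams(particles_per_pixel_per_day=4, replicates=1, seed=0)

events = run_experiment(grid, flow, schedule, params)
print(f"released {len(events)} particles, {int((events.fate == 'settled').sum())} settled")

def rearward(ev):
    return rearward_probability(bin_by_island(settlement_matrix(ev, grid), grid))

P_year = rearward(events)
P_spawn = rearward(filter_by_release_months(events, {5, 6}))

np.set_printoptions(precision=3, suppress=True)
print("\nrearward matrix, all releases:")
print(P_year.values)
print("\nrearward matrix, May-June releases only:")
print(P_spawn.values)
print("\ndifference (year-round minus May-June):")
print(matrix_difference(P_year, P_spawn))
res = mantel_test(P_year, P_spawn, n_perm=999, seed=1)
print(f"\nmantel r = {res.r:.3f}, one-sided p = {res.p:.3f} ({res.n_perm} permutations)")
print(
    "\nA high r says the seasonal subset preserves the year-round\n"
    "connectivity pattern; the difference matrix shows where island pairs\n"
    "gain or lose transport probability.  (With only 3 islands there are\n"
    "just 6 distinct relabelings, so the permutation p-value is coarse —\n"
    "island counts like the real archipelago's 31 make it informative.)"
)
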