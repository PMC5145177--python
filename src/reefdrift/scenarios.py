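"""Named synthetic scenarios with analytically known connectivity.

Real archipelago-scale inputs (satellite-derived habitat maps, circulation
model output) are large and not redistributable, so the pipeline is
exercised on constructed island chains and flow fields whose expected
connectivity structure is known in closed form:

``conveyor``
    A linear chain at constant latitude with a uniform zonal current tuned
    so each island's particles land exactly on the next island downstream
    (K = 0).  Expected island matrix: pure superdiagonal.
``broken_chain``
    The conveyor with one inter-island gap widened beyond the transport
    range — an engineered connectivity break with exactly zero flux across
    the gap.
``isolated_atoll``
    A chain plus one island placed far beyond the 45-day advective +
    3-sigma diffusive range.  Any settler at the isolated island must be a
    self-recruit: self-recruitment 1.0, source–sink index 0.
``diffusion_only``
    Zero velocity, configurable K: displacement variance 2·K·t per axis,
    used for diffusivity parameter recovery.

The module also provides the dense-small-step brute-force integrator used
as an independent oracle for deterministic (K = 0) runs, and the
moment-based eddy-diffusivity estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow_fields import AnalyticFlowField, Domain, make_analytic_flow
from .habitat import (
    EARTH_RADIUS_KM,
    METERS_PER_DEGREE,
    HabitatGrid,
    haversine_km,
    nearest_pixels,
    normalize_lon,
)
from .tracker import SECONDS_PER_DAY, ReleaseSchedule, RunParams
from .connectivity import SettlementMatrix

SCENARIO_NAMES = ("isolated_atoll", "conveyor", "broken_chain", "diffusion_only")


@dataclass
class Scenario:
    """A habitat + flow + schedule + parameters bundle with known outcomes.

    ``expected`` maps metric names to analytically forced values or
    Monte-Carlo targets (with their tolerance stated where stochastic).
    """

    name: str
    grid: HabitatGrid
    flow: AnalyticFlowField
    schedule: ReleaseSchedule
    params: RunParams
    expected: dict = field(default_factory=dict)


def destination_point(lon, lat, bearing_deg, distance_km, radius_km=EARTH_RADIUS_KM):
    """Great-circle forward geodesic: point at a bearing and distance."""
    delta = distance_km / radius_km
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return float(normalize_lon(np.degrees(lam2))), float(np.degrees(phi2))


def _pixel_offsets(n_pixels: int, pixel_spacing_km: float):
    """Compact ~square grid of (dx, dy) offsets in km, centered on (0, 0)."""
    ncols = int(np.ceil(np.sqrt(n_pixels)))
    xs, ys = [], []
    for k in range(n_pixels):
        r, c = divmod(k, ncols)
        xs.append(c * pixel_spacing_km)
        ys.append(r * pixel_spacing_km)
    xs = np.array(xs) - np.mean(xs)
    ys = np.array(ys) - np.mean(ys)
    return xs, ys


def make_archipelago(
    n_islands: int,
    pixels_per_island: int,
    spacing_km: float,
    bearing_deg: float = 90.0,
    origin=(200.0, 20.0),
    pixel_spacing_km: float = 2.0,
    constant_latitude: bool = False,
) -> HabitatGrid:
    """Linear island chain along a great-circle bearing.

    Each island is a compact ~``pixel_spacing_km`` grid of pixels around
    its center; island centers sit ``spacing_km`` apart along the chain.
    With ``constant_latitude=True`` the centers are instead placed at equal
    longitude increments along the origin's parallel (the spacing then
    measures arc length along that parallel) — useful when a zonal current
    must map centers exactly onto one another.
    """
    if n_islands <= 0 or pixels_per_island <= 0 or spacing_km <= 0:
        raise ValueError("n_islands, pixels_per_island and spacing_km must be positive")
    if spacing_km < 2.0:
        raise ValueError("spacing_km must be at least 2 km")
    footprint = (np.ceil(np.sqrt(pixels_per_island)) - 1) * pixel_spacing_km
    if n_islands > 1 and spacing_km <= footprint * np.sqrt(2.0) + 2.0:
        raise ValueError("islands geometrically overlap: spacing smaller than island footprint")

    lon0, lat0 = origin
    if constant_latitude:
        dlon = spacing_km * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
        centers = [(normalize_lon(lon0 + k * dlon), lat0) for k in range(n_islands)]
    else:
        centers = [destination_point(lon0, lat0, bearing_deg, k * spacing_km) for k in range(n_islands)]

    dx, dy = _pixel_offsets(pixels_per_island, pixel_spacing_km)
    lons, lats, isl = [], [], []
    for i, (clon, clat) in enumerate(centers):
        lons.extend(clon + dx * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(clat))))
        lats.extend(clat + dy * 1000.0 / METERS_PER_DEGREE)
        isl.extend([i] * pixels_per_island)
    return HabitatGrid.from_arrays(lons, lats, isl)


def _chain_domain(grid: HabitatGrid, margin_deg: float) -> Domain:
    return Domain(
        grid.lons.min() - margin_deg,
        grid.lons.max() + margin_deg,
        max(grid.lats.min() - margin_deg, -89.0),
        min(grid.lats.max() + margin_deg, 89.0),
    )


def _conveyor_parts(n_islands, pixels_per_island, spacing_km, lat0, lon0, params, gap_after=None, gap_factor=3.0):
    """Chain habitat + uniform flow carrying particles one spacing downstream."""
    dlon = spacing_km * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
    offsets = []
    pos = 0.0
    for k in range(n_islands):
        offsets.append(pos)
        pos += dlon * (gap_factor if (gap_after is not None and k == gap_after) else 1.0)
    dx, dy = _pixel_offsets(pixels_per_island, 2.0)
    lons, lats, isl = [], [], []
    for i, off in enumerate(offsets):
        clon, clat = lon0 + off, lat0
        lons.extend(clon + dx * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(clat))))
        lats.extend(clat + dy * 1000.0 / METERS_PER_DEGREE)
        isl.extend([i] * pixels_per_island)
    grid = HabitatGrid.from_arrays(lons, lats, isl)

    T = params.pld_days * SECONDS_PER_DAY
    u0 = dlon * METERS_PER_DEGREE * np.cos(np.radians(lat0)) / T
    # domain wide enough that the last island's particles stay in-grid (lost_unsettled)
    margin = 2.0 * dlon * max(1.0, gap_factor) + 1.0
    dom = Domain(lon0 - 1.0, lon0 + offsets[-1] + margin, lat0 - 2.0, lat0 + 2.0)
    flow = make_analytic_flow("uniform", {"u0": u0, "v0": 0.0}, dom)
    return grid, flow


def scenario(name: str, **kw) -> Scenario:
    """Build a named scenario (see module docstring for the catalogue).

    Keyword arguments override scenario-specific defaults; common ones are
    ``n_islands``, ``pixels_per_island``, ``spacing_km``, ``seed``, and any
    :class:`~reefdrift.tracker.RunParams` field via ``params``.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    seed = int(kw.pop("seed", 0))
    schedule = kw.pop("schedule", ReleaseSchedule.daily("2009-05-02", "2009-05-02"))

    if name == "conveyor":
        n_islands = kw.pop("n_islands", 4)
        ppi = kw.pop("pixels_per_island", 1)
        spacing = kw.pop("spacing_km", 60.0)
        lat0 = kw.pop("lat0", 20.0)
        lon0 = kw.pop("lon0", 200.0)
        params = kw.pop("params", None) or RunParams(
            eddy_diffusivity=0.0, replicates=1, particles_per_pixel_per_day=20, seed=seed
        )
        if params.eddy_diffusivity != 0:
            raise ValueError("conveyor expects K=0 (deterministic geometry)")
        grid, flow = _conveyor_parts(n_islands, ppi, spacing, lat0, lon0, params)
        per_link = params.particles_per_pixel_per_day * ppi * schedule.n_dates * params.replicates
        exp_matrix = np.zeros((n_islands, n_islands))
        for k in range(n_islands - 1):
            exp_matrix[k, k + 1] = per_link
        expected = {"island_matrix": exp_matrix}
        return Scenario(name, grid, flow, schedule, params, expected)

    if name == "broken_chain":
        n_islands = kw.pop("n_islands", 4)
        ppi = kw.pop("pixels_per_island", 1)
        spacing = kw.pop("spacing_km", 60.0)
        gap_after = kw.pop("gap_after", 1)
        gap_factor = kw.pop("gap_factor", 3.0)
        lat0 = kw.pop("lat0", 20.0)
        lon0 = kw.pop("lon0", 200.0)
        if not (0 <= gap_after < n_islands - 1):
            raise ValueError("gap_after must index an internal link")
        if gap_factor <= 1.5:
            raise ValueError("gap_factor must widen the gap well beyond reach")
        params = kw.pop("params", None) or RunParams(
            eddy_diffusivity=0.0, replicates=1, particles_per_pixel_per_day=20, seed=seed
        )
        if params.eddy_diffusivity != 0:
            raise ValueError("broken_chain expects K=0")
        grid, flow = _conveyor_parts(n_islands, ppi, spacing, lat0, lon0, params, gap_after, gap_factor)
        per_link = params.particles_per_pixel_per_day * ppi * schedule.n_dates * params.replicates
        exp_matrix = np.zeros((n_islands, n_islands))
        for k in range(n_islands - 1):
            if k != gap_after:
                exp_matrix[k, k + 1] = per_link
        expected = {"island_matrix": exp_matrix, "gap_after": gap_after}
        return Scenario(name, grid, flow, schedule, params, expected)

    if name == "isolated_atoll":
        n_chain = kw.pop("n_chain_islands", 3)
        ppi = kw.pop("pixels_per_island", 4)
        iso_pixels = kw.pop("isolated_pixels", 9)
        spacing = kw.pop("spacing_km", 60.0)
        separation = kw.pop("separation_km", 2000.0)
        lat0 = kw.pop("lat0", 20.0)
        lon0 = kw.pop("lon0", 185.0)
        params = kw.pop("params", None) or RunParams(
            replicates=1, particles_per_pixel_per_day=100, seed=seed
        )
        # weak retention flow: still water; only diffusion moves particles
        chain = make_archipelago(n_chain, ppi, spacing, origin=(lon0, lat0), constant_latitude=True)
        iso_lon = normalize_lon(
            chain.lons.max() + separation * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
        )
        dx, dy = _pixel_offsets(iso_pixels, 2.0)
        lons = np.concatenate(
            [chain.lons, iso_lon + dx * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))]
        )
        lats = np.concatenate([chain.lats, lat0 + dy * 1000.0 / METERS_PER_DEGREE])
        isl = np.concatenate([chain.island_ids, np.full(iso_pixels, n_chain)])
        grid = HabitatGrid.from_arrays(lons, lats, isl)

        # reachability guard: separation must dwarf advective + 3-sigma diffusive range
        T = params.pld_days * SECONDS_PER_DAY
        sigma_km = np.sqrt(2.0 * params.eddy_diffusivity * T) / 1000.0
        reach_km = 3.0 * sigma_km * np.sqrt(2.0)  # advective part is zero here
        min_sep = haversine_km(chain.lons.max(), lat0, iso_lon, lat0)
        if min_sep < 10.0 * max(reach_km, 1e-9):
            raise ValueError(
                f"isolated island only {min_sep:.0f} km from the chain; "
                f"needs >= 10x the {reach_km:.0f} km transport range"
            )
        dom = _chain_domain(grid, 4.0)
        flow = make_analytic_flow("uniform", {"u0": 0.0, "v0": 0.0}, dom)
        expected = {"isolated_island": n_chain, "self_recruitment": 1.0, "source_sink_index": 0.0}
        return Scenario(name, grid, flow, schedule, params, expected)

    # diffusion_only
    K = kw.pop("eddy_diffusivity", 250.0)
    lat0 = kw.pop("lat0", 20.0)
    lon0 = kw.pop("lon0", 200.0)
    params = kw.pop("params", None) or RunParams(
        eddy_diffusivity=K, replicates=1, particles_per_pixel_per_day=100, seed=seed
    )
    grid = HabitatGrid.from_arrays([lon0], [lat0], [0])
    dom = Domain(lon0 - 8.0, lon0 + 8.0, lat0 - 8.0, lat0 + 8.0)
    flow = make_analytic_flow("uniform", {"u0": 0.0, "v0": 0.0}, dom)
    expected = {
        "per_axis_variance_m2": lambda t_s: 2.0 * params.eddy_diffusivity * t_s,
        "eddy_diffusivity": params.eddy_diffusivity,
    }
    return Scenario("diffusion_only", grid, flow, schedule, params, expected)


# ---------------------------------------------------------------------------
# estimators and oracles
# ---------------------------------------------------------------------------


def estimate_diffusivity(dx_m, dy_m, elapsed_seconds: float) -> float:
    """Moment estimator of K from zero-mean-flow displacements.

    K̂ = (var(dx) + var(dy)) / (4 t): the per-axis displacement variance of
    a random walk is 2·K·t, and the two axes are averaged.
    """
    if elapsed_seconds <= 0:
        raise ValueError("elapsed_seconds must be positive")
    dx_m = np.asarray(dx_m, dtype=float)
    dy_m = np.asarray(dy_m, dtype=float)
    if dx_m.size < 100:
        raise ValueError("need at least 100 displacement samples")
    var = np.var(dx_m, ddof=1) + np.var(dy_m, ddof=1)
    return float(var / (4.0 * elapsed_seconds))


def diffusion_displacements(n: int, elapsed_days: float, seed: int, eddy_diffusivity: float = 250.0,
                            lon0: float = 200.0, lat0: float = 20.0, dt_seconds: int = 3600):
    """Run the tracker in still water and return per-axis displacements (m).

    Releases ``n`` particles at one point, integrates ``elapsed_days`` of
    pure diffusion, and converts the final lon/lat offsets back to metres
    at the release latitude.  Feed the result to
    :func:`estimate_diffusivity` for end-to-end parameter recovery.
    """
    from .tracker import integrate_particles

    sc = scenario("diffusion_only", eddy_diffusivity=eddy_diffusivity, lon0=lon0, lat0=lat0)
    params = RunParams(
        pld_days=int(elapsed_days),
        eddy_diffusivity=eddy_diffusivity,
        dt_seconds=dt_seconds,
        replicates=1,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0, 0]))
    lon = np.full(n, lon0, dtype=float)
    lat = np.full(n, lat0, dtype=float)
    lonf, latf = integrate_particles(lon, lat, sc.flow, sc.schedule.dates[0], params, rng)
    dlon = (lonf - lon0 + 180.0) % 360.0 - 180.0
    dx = dlon * METERS_PER_DEGREE * np.cos(np.radians(lat0))
    dy = (latf - lat0) * METERS_PER_DEGREE
    ok = np.isfinite(dx) & np.isfinite(dy)
    return dx[ok], dy[ok], elapsed_days * SECONDS_PER_DAY


def brute_force_connectivity(sc: Scenario, dt_seconds: float = 60.0) -> SettlementMatrix:
    """Independent dense-step Euler oracle for deterministic scenarios.

    Integrates each habitat pixel's single deterministic trajectory with a
    small-step forward Euler scheme written independently of the main
    tracker, applies the settlement rule to the day-PLD endpoint, and
    scales counts by the release multiplicity.  Only valid for K = 0.
    """
    params = sc.params
    if params.eddy_diffusivity != 0:
        raise ValueError("brute-force oracle requires K=0 (deterministic run)")
    grid, flow = sc.grid, sc.flow
    T = params.pld_days * SECONDS_PER_DAY
    n_steps = int(round(T / dt_seconds))

    lon = grid.lons.copy()
    lat = grid.lats.copy()
    for k in range(n_steps):
        u, v = flow.sample(lon, lat, k * dt_seconds)
        lon = normalize_lon(lon + dt_seconds * u / (METERS_PER_DEGREE * np.cos(np.radians(lat))))
        lat = lat + dt_seconds * v / METERS_PER_DEGREE
        inside = flow.domain.contains(lon, lat)
        lon = np.where(inside, lon, np.nan)
        lat = np.where(inside, lat, np.nan)

    settle = nearest_pixels(grid, lon, lat, params.settle_radius_km)
    mult = params.particles_per_pixel_per_day * sc.schedule.n_dates * params.replicates
    n = grid.n_pixels
    S = np.zeros((n, n))
    for i in range(n):
        if settle[i] >= 0:
            S[i, settle[i]] += mult
    pix = SettlementMatrix(S, list(range(n)), "pixel")
    from .connectivity import bin_by_island

    return bin_by_island(pix, grid)
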