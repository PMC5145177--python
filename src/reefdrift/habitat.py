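"""Reef habitat grids and great-circle distance utilities.

Habitat is represented as a flat table of reef *pixels* — the centers of
roughly 2 km squares of suitable settlement habitat — each assigned to an
*island* group so that pixel-level simulation output can be aggregated to
island-level connectivity statistics.  Longitudes are kept on the [0, 360)
convention throughout so that archipelagos spanning the antimeridian need no
special casing in interpolation or distance code.

Distances are great-circle (haversine) kilometres on a sphere of radius
:data:`EARTH_RADIUS_KM`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mean Earth radius in kilometres used for every geodesic computation.
#: Exposed as a module constant (and as a keyword argument on the distance
#: functions) so that an alternative convention, e.g. the WGS84 equatorial
#: radius 6378.137 km, can be substituted.
EARTH_RADIUS_KM = 6371.0

#: Metres per degree of latitude (and of longitude at the equator) on the
#: reference sphere: pi * R / 180, in metres.
METERS_PER_DEGREE = 1000.0 * np.pi * EARTH_RADIUS_KM / 180.0

HABITAT_COLUMNS = ["pixel_id", "lon_deg", "lat_deg", "island_id", "island_name"]


def normalize_lon(lon):
    """Map longitudes (scalar or array, degrees) onto [0, 360)."""
    return np.mod(lon, 360.0)


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in degrees.

    Broadcasts over array inputs.  Uses the haversine formula, which is
    numerically stable for small separations.

    Raises
    ------
    ValueError
        If any latitude lies outside [-90, 90].
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    if np.any(np.abs(lat1) > 90.0) or np.any(np.abs(lat2) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * radius_km * np.arcsin(np.sqrt(a))


@dataclass
class HabitatGrid:
    """Validated table of reef pixel centers with island grouping.

    The underlying table has columns ``pixel_id`` (contiguous integers from
    0), ``lon_deg`` ([0, 360)), ``lat_deg``, ``island_id`` and
    ``island_name``.  Island ordering is fixed by first appearance in
    pixel_id order and is stable across I/O round trips.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in HABITAT_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"habitat table missing columns: {missing}")
        t = t[HABITAT_COLUMNS].copy()
        if len(t) == 0:
            raise ValueError("habitat table is empty")
        pid = t["pixel_id"].to_numpy()
        if len(np.unique(pid)) != len(pid):
            raise ValueError("duplicate pixel_id in habitat table")
        t = t.sort_values("pixel_id").reset_index(drop=True)
        if not np.array_equal(t["pixel_id"].to_numpy(), np.arange(len(t))):
            raise ValueError("pixel_id must be contiguous integers starting at 0")
        if t["island_id"].isna().any():
            raise ValueError("every pixel needs an island_id")
        if np.any(np.abs(t["lat_deg"].to_numpy(dtype=float)) > 90.0):
            raise ValueError("latitude out of range [-90, 90]")
        t["lon_deg"] = normalize_lon(t["lon_deg"].to_numpy(dtype=float))
        t["lat_deg"] = t["lat_deg"].astype(float)
        t["island_id"] = t["island_id"].astype(int)
        t["island_name"] = t["island_name"].astype(str)
        self.table = t

    # -- convenience accessors -------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.table)

    @property
    def lons(self) -> np.ndarray:
        return self.table["lon_deg"].to_numpy()

    @property
    def lats(self) -> np.ndarray:
        return self.table["lat_deg"].to_numpy()

    @property
    def island_ids(self) -> np.ndarray:
        return self.table["island_id"].to_numpy()

    @property
    def islands(self) -> pd.DataFrame:
        """Distinct islands in first-appearance order (the plotting order)."""
        seen = self.table.drop_duplicates("island_id", keep="first")
        return seen[["island_id", "island_name"]].reset_index(drop=True)

    @property
    def n_islands(self) -> int:
        return len(self.islands)

    @property
    def island_names(self) -> list[str]:
        return self.islands["island_name"].tolist()

    def island_index(self) -> np.ndarray:
        """Per-pixel position of its island in first-appearance order."""
        order = {iid: k for k, iid in enumerate(self.islands["island_id"])}
        return np.array([order[i] for i in self.island_ids], dtype=int)

    @classmethod
    def from_arrays(cls, lon, lat, island_id, island_name=None) -> "HabitatGrid":
        lon = np.asarray(lon, dtype=float)
        island_id = np.asarray(island_id, dtype=int)
        if island_name is None:
            island_name = [f"I{str(i).zfill(2)}" for i in island_id]
        return cls(
            pd.DataFrame(
                {
                    "pixel_id": np.arange(len(lon)),
                    "lon_deg": lon,
                    "lat_deg": np.asarray(lat, dtype=float),
                    "island_id": island_id,
                    "island_name": island_name,
                }
            )
        )


def load_habitat_table(path) -> HabitatGrid:
    """Read a habitat CSV (header ``pixel_id,lon_deg,lat_deg,island_id,island_name``).

    Longitudes may be given on either [-180, 180) or [0, 360); they are
    stored on [0, 360).
    """
    return HabitatGrid(pd.read_csv(path))


def save_habitat_table(grid: HabitatGrid, path) -> None:
    grid.table.to_csv(path, index=False)


def pixel_distance_matrix(grid: HabitatGrid, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """All-pairs great-circle distance matrix (km) in pixel_id order.

    Symmetric with a zero diagonal; entry (i, j) is the haversine distance
    between pixel centers i and j.
    """
    lon, lat = grid.lons, grid.lats
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :], radius_km)
    np.fill_diagonal(d, 0.0)
    return d


def save_distance_matrix(d: np.ndarray, path) -> None:
    n = d.shape[0]
    pd.DataFrame(d, index=np.arange(n), columns=np.arange(n)).to_csv(path, index_label="pixel_id")


#: Absolute tolerance (km) within which two candidate settlement distances
#: are considered tied; ties resolve to the lowest pixel_id.
TIE_TOL_KM = 1e-9


def nearest_pixels(grid: HabitatGrid, lons, lats, max_radius_km: float) -> np.ndarray:
    """Vectorized nearest-habitat-pixel assignment.

    For each query position, returns the pixel_id of the nearest pixel
    center if it lies within ``max_radius_km``, else -1.  Ties within
    :data:`TIE_TOL_KM` go to the lowest pixel_id.  Non-finite query
    positions return -1.
    """
    if max_radius_km <= 0:
        raise ValueError("max_radius_km must be positive")
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    out = np.full(lons.shape, -1, dtype=int)
    ok = np.isfinite(lons) & np.isfinite(lats)
    if not np.any(ok):
        return out
    d = haversine_km(lons[ok, None], lats[ok, None], grid.lons[None, :], grid.lats[None, :])
    dmin = d.min(axis=1)
    # first index within tolerance of the minimum == lowest pixel_id
    pick = (d <= (dmin + TIE_TOL_KM)[:, None]).argmax(axis=1)
    pick = np.where(dmin <= max_radius_km, pick, -1)
    out[ok] = pick
    return out


def nearest_pixel(grid: HabitatGrid, pos, max_radius_km: float):
    """Scalar convenience wrapper around :func:`nearest_pixels`.

    ``pos`` is a (lon, lat) pair in degrees.  Returns a pixel_id or None.
    """
    pid = nearest_pixels(grid, [pos[0]], [pos[1]], max_radius_km)[0]
    return None if pid < 0 else int(pid)
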