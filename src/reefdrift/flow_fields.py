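"""Horizontal velocity fields that advect virtual larvae.

Two families of field are supported behind one sampling interface:

* **Analytic fields** — closed-form (lon, lat) -> (u, v) functions
  (uniform flow, solid-body eddy, zonal jet, double gyre) used to build
  synthetic circulation with known transport geometry.
* **Gridded fields** — single-layer (2-D) velocity snapshots on a regular
  lon/lat grid, optionally time-varying, as exported by ocean circulation
  models.  Sampling is bilinear in space and linear in time.

All fields are two-dimensional: tracking follows a single model layer.
Velocities are in m/s; longitudes are internally on [0, 360).  Queries
outside the spatial domain (or touching masked land cells of a gridded
field) return NaN rather than extrapolating — the tracker treats such
particles as lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .habitat import normalize_lon

#: Sanity cap on analytic field speeds (m/s); ocean currents never approach
#: this, so larger configured values are treated as misconfiguration.
MAX_SPEED = 5.0

#: Unit strings accepted for gridded velocity variables.
_VELOCITY_UNITS = {"m s-1", "m/s", "m s^-1", "meter second-1"}

ANALYTIC_KINDS = ("uniform", "solid_body_eddy", "zonal_jet", "double_gyre")

_REQUIRED_PARAMS = {
    "uniform": {"u0", "v0"},
    "solid_body_eddy": {"center_lon", "center_lat", "radius_km", "peak_speed"},
    "zonal_jet": {"lat0", "width_km", "speed"},
    "double_gyre": {"amplitude"},
}

_M_PER_DEG = 1000.0 * np.pi * 6371.0 / 180.0


def to_epoch_seconds(t) -> float:
    """Convert a timestamp-like value to float seconds since the Unix epoch.

    Floats/ints pass through unchanged (already epoch seconds).
    """
    if t is None:
        return 0.0
    if isinstance(t, (int, float, np.integer, np.floating)):
        return float(t)
    return float(np.datetime64(pd.Timestamp(t)).astype("datetime64[s]").astype(np.int64))


@dataclass(frozen=True)
class Domain:
    """Rectangular lon/lat domain, longitudes on [0, 360).

    A domain crossing the antimeridian is expressed with lon_min < lon_max
    after mapping to [0, 360), e.g. 175°E..150°W becomes (175, 210).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        lo = float(normalize_lon(self.lon_min))
        hi = float(normalize_lon(self.lon_max))
        if hi == 0.0 and self.lon_max in (360, 360.0):
            hi = 360.0
        object.__setattr__(self, "lon_min", lo)
        object.__setattr__(self, "lon_max", hi)
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max after mapping to [0, 360)")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")

    def contains(self, lon, lat):
        lon = normalize_lon(np.asarray(lon, dtype=float))
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


class FlowField:
    """Base class: anything that can be sampled for (u, v) in m/s."""

    domain: Domain
    kind: str

    @property
    def is_steady(self) -> bool:
        raise NotImplementedError

    def sample(self, lon, lat, t=None):
        """Velocity (u, v) in m/s at positions (degrees) and time t.

        NaN marks off-domain queries (and masked land cells for gridded
        fields).  ``t`` may be a timestamp, epoch seconds, or None for
        steady fields.
        """
        raise NotImplementedError


class AnalyticFlowField(FlowField):
    """Steady closed-form velocity field defined everywhere in its domain.

    Supported kinds and parameters (all speeds m/s):

    ``uniform``
        ``u0``, ``v0`` — constant eastward/northward components.
    ``solid_body_eddy``
        ``center_lon``, ``center_lat``, ``radius_km``, ``peak_speed`` —
        counterclockwise rotation with tangential speed growing linearly
        to ``peak_speed`` at ``radius_km`` (Rankine core) and decaying as
        1/r outside.
    ``zonal_jet``
        ``lat0``, ``width_km``, ``speed`` — eastward Gaussian jet,
        u = speed * exp(-((lat - lat0)_km / width_km)^2).
    ``double_gyre``
        ``amplitude`` — the classic two-cell recirculation on the domain
        rectangle, peak speed = amplitude.
    """

    def __init__(self, kind: str, params: dict, domain: Domain):
        if kind not in ANALYTIC_KINDS:
            raise ValueError(f"unknown analytic flow kind: {kind!r}")
        missing = _REQUIRED_PARAMS[kind] - set(params)
        if missing:
            raise ValueError(f"{kind} flow missing parameters: {sorted(missing)}")
        speeds = {
            "uniform": lambda p: np.hypot(p["u0"], p["v0"]),
            "solid_body_eddy": lambda p: abs(p["peak_speed"]),
            "zonal_jet": lambda p: abs(p["speed"]),
            "double_gyre": lambda p: abs(p["amplitude"]),
        }
        if speeds[kind](params) > MAX_SPEED:
            raise ValueError(f"configured speed exceeds {MAX_SPEED} m/s; rejected as misconfiguration")
        if kind == "solid_body_eddy" and params["radius_km"] <= 0:
            raise ValueError("eddy radius_km must be positive")
        if kind == "zonal_jet" and params["width_km"] <= 0:
            raise ValueError("jet width_km must be positive")
        self.kind = kind
        self.params = dict(params)
        self.domain = domain

    @property
    def is_steady(self) -> bool:
        return True

    def sample(self, lon, lat, t=None):
        lon = normalize_lon(np.asarray(lon, dtype=float))
        lat = np.asarray(lat, dtype=float)
        u, v = self._evaluate(lon, lat)
        inside = self.domain.contains(lon, lat)
        u = np.where(inside, u, np.nan)
        v = np.where(inside, v, np.nan)
        return u, v

    def _evaluate(self, lon, lat):
        p = self.params
        if self.kind == "uniform":
            shape = np.broadcast(lon, lat).shape
            return np.full(shape, float(p["u0"])), np.full(shape, float(p["v0"]))
        if self.kind == "solid_body_eddy":
            # local tangent-plane offsets from the eddy center, km
            dlon = (lon - normalize_lon(p["center_lon"]) + 180.0) % 360.0 - 180.0
            dx = dlon * np.cos(np.radians(p["center_lat"])) * _M_PER_DEG / 1000.0
            dy = (lat - p["center_lat"]) * _M_PER_DEG / 1000.0
            r = np.hypot(dx, dy)
            R = float(p["radius_km"])
            speed = np.where(r <= R, p["peak_speed"] * r / R, p["peak_speed"] * R / np.maximum(r, 1e-12))
            with np.errstate(invalid="ignore", divide="ignore"):
                u = np.where(r > 0, -speed * dy / np.maximum(r, 1e-12), 0.0)
                v = np.where(r > 0, speed * dx / np.maximum(r, 1e-12), 0.0)
            return u, v
        if self.kind == "zonal_jet":
            off_km = (lat - p["lat0"]) * _M_PER_DEG / 1000.0
            u = p["speed"] * np.exp(-((off_km / p["width_km"]) ** 2))
            return u, np.zeros_like(u)
        # double_gyre: streamfunction-style two-cell pattern on the unit box
        d = self.domain
        x = 2.0 * (lon - d.lon_min) / (d.lon_max - d.lon_min)
        y = (lat - d.lat_min) / (d.lat_max - d.lat_min)
        A = float(p["amplitude"])
        u = -A * np.sin(np.pi * x) * np.cos(np.pi * y)
        v = A * np.cos(np.pi * x) * np.sin(np.pi * y)
        return u, v

    def to_config(self) -> dict:
        d = self.domain
        return {
            "kind": self.kind,
            "params": {k: float(v) for k, v in self.params.items()},
            "domain": {
                "lon_min": d.lon_min,
                "lon_max": d.lon_max,
                "lat_min": d.lat_min,
                "lat_max": d.lat_max,
            },
        }


def make_analytic_flow(kind: str, params: dict, domain: Domain) -> AnalyticFlowField:
    """Construct a named analytic velocity field (see :class:`AnalyticFlowField`)."""
    return AnalyticFlowField(kind, params, domain)


def flow_from_config(block: dict) -> AnalyticFlowField:
    """Rebuild an analytic field from its serialized config block."""
    dom = Domain(**block["domain"])
    return make_analytic_flow(block["kind"], block["params"], dom)


def _normalize_lon_axis(lon_axis: np.ndarray, *fields):
    """Map a longitude axis to [0, 360), rolling at the wrap if needed.

    Returns the new axis plus the fields reordered along their last axis.
    """
    lon = normalize_lon(np.asarray(lon_axis, dtype=float))
    if np.all(np.diff(lon) > 0):
        return (lon, *fields)
    wraps = np.where(np.diff(lon) < 0)[0]
    if len(wraps) != 1:
        raise ValueError("longitude axis is not monotonic")
    k = wraps[0] + 1
    order = np.r_[k : len(lon), 0:k]
    lon = lon[order]
    if not np.all(np.diff(lon) > 0):
        raise ValueError("longitude axis is not monotonic after [0,360) mapping")
    return (lon, *(f[..., order] for f in fields))


class GriddedFlowField(FlowField):
    """Single-layer velocity snapshots on a regular lon/lat(/time) grid.

    ``u`` and ``v`` are arrays shaped (time, lat, lon), or (lat, lon) for a
    steady field.  Land / missing cells are NaN and poison any sample that
    touches them.  Sampling interpolates bilinearly in space and linearly
    in time, and returns NaN outside the grid (no extrapolation).
    """

    def __init__(self, lon_axis, lat_axis, u, v, time_axis=None):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        lat_axis = np.asarray(lat_axis, dtype=float)
        lon_axis, u, v = _normalize_lon_axis(lon_axis, u, v)
        if not np.all(np.diff(lat_axis) > 0):
            raise ValueError("latitude axis must be strictly increasing")
        if time_axis is not None:
            time_axis = np.asarray(time_axis, dtype="datetime64[s]")
            if len(time_axis) > 1 and not np.all(np.diff(time_axis).astype(int) > 0):
                raise ValueError("time axis must be strictly increasing")
            if u.shape != (len(time_axis), len(lat_axis), len(lon_axis)):
                raise ValueError("u shape does not match (time, lat, lon) axes")
        else:
            if u.shape != (len(lat_axis), len(lon_axis)):
                raise ValueError("u shape does not match (lat, lon) axes")
        if v.shape != u.shape:
            raise ValueError("u and v shapes differ")
        if np.any(np.isinf(u)) or np.any(np.isinf(v)):
            raise ValueError("velocity values must be finite or NaN (land mask)")
        self.kind = "gridded"
        self.lon_axis = lon_axis
        self.lat_axis = lat_axis
        self.time_axis = time_axis if (time_axis is not None and len(time_axis) > 1) else None
        if time_axis is not None and len(time_axis) == 1:
            u, v = u[0], v[0]
        self.u = u
        self.v = v
        self.domain = Domain(lon_axis[0], lon_axis[-1], lat_axis[0], lat_axis[-1])
        if self.time_axis is None:
            pts = (self.lat_axis, self.lon_axis)
        else:
            self._t0 = self.time_axis.astype(np.int64)
            pts = (self._t0.astype(float), self.lat_axis, self.lon_axis)
        self._ui = RegularGridInterpolator(pts, self.u, bounds_error=False, fill_value=np.nan)
        self._vi = RegularGridInterpolator(pts, self.v, bounds_error=False, fill_value=np.nan)

    @property
    def is_steady(self) -> bool:
        return self.time_axis is None

    def time_span(self):
        if self.time_axis is None:
            return None
        return self.time_axis[0], self.time_axis[-1]

    def sample(self, lon, lat, t=None):
        lon = normalize_lon(np.asarray(lon, dtype=float))
        lat = np.asarray(lat, dtype=float)
        shape = np.broadcast(lon, lat).shape
        lon, lat = np.broadcast_arrays(lon, lat)
        if self.time_axis is None:
            pts = np.column_stack([lat.ravel(), lon.ravel()])
        else:
            if t is None:
                raise ValueError("time-varying field requires a sample time t")
            ts = to_epoch_seconds(t)
            pts = np.column_stack([np.full(lon.size, ts), lat.ravel(), lon.ravel()])
        u = self._ui(pts).reshape(shape)
        v = self._vi(pts).reshape(shape)
        return u, v

    def to_dataset(self) -> xr.Dataset:
        if self.time_axis is None:
            coords = {"lat": self.lat_axis, "lon": self.lon_axis}
            dims = ("lat", "lon")
            u, v = self.u, self.v
        else:
            coords = {"time": self.time_axis, "lat": self.lat_axis, "lon": self.lon_axis}
            dims = ("time", "lat", "lon")
            u, v = self.u, self.v
        ds = xr.Dataset(
            {"u": (dims, u), "v": (dims, v)},
            coords=coords,
        )
        for name in ("u", "v"):
            ds[name].attrs["units"] = "m s-1"
        ds["lon"].attrs["units"] = "degrees_east"
        ds["lat"].attrs["units"] = "degrees_north"
        return ds


def sample_velocity(flow: FlowField, lon, lat, t=None):
    """Sample (u, v) in m/s from any flow field; NaN = off-grid/masked."""
    return flow.sample(lon, lat, t)


def read_gridded_flow(path) -> GriddedFlowField:
    """Read a gridded velocity file into a :class:`GriddedFlowField`.

    Two dialects are accepted:

    * classic NetCDF with dims (time, lat, lon) (or just (lat, lon)),
      variables ``u`` and ``v`` carrying a units attribute of ``m s-1``
      (``m/s`` also accepted — anything else is a hard error, no silent
      conversion), coordinates in degrees, NaN/missing-value land mask;
    * a plain-text CSV fallback for a single steady snapshot with columns
      ``lon,lat,u,v`` (assumed m/s) on a complete regular grid.
    """
    path = str(path)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        for c in ("lon", "lat", "u", "v"):
            if c not in df.columns:
                raise ValueError(f"flow CSV missing column {c!r}")
        df["lon"] = normalize_lon(df["lon"].to_numpy(dtype=float))
        lons = np.unique(df["lon"])
        lats = np.unique(df["lat"])
        if len(df) != len(lons) * len(lats):
            raise ValueError("flow CSV is not a complete regular grid")
        pu = df.pivot_table(index="lat", columns="lon", values="u").to_numpy()
        pv = df.pivot_table(index="lat", columns="lon", values="v").to_numpy()
        return GriddedFlowField(lons, lats, pu, pv)

    ds = xr.open_dataset(path, engine="scipy")
    try:
        for name in ("u", "v"):
            if name not in ds:
                raise ValueError(f"gridded flow file missing variable {name!r}")
            units = ds[name].attrs.get("units", "")
            if units not in _VELOCITY_UNITS:
                raise ValueError(
                    f"variable {name!r} has units {units!r}; expected m s-1 (no silent conversion)"
                )
        u = ds["u"]
        time_axis = ds["time"].values if "time" in u.dims else None
        uv = u.values
        vv = ds["v"].values
        if time_axis is None and uv.ndim == 3:
            raise ValueError("3-D velocity variable without a time coordinate")
        return GriddedFlowField(ds["lon"].values, ds["lat"].values, uv, vv, time_axis=time_axis)
    finally:
        ds.close()


def write_gridded_flow(field: GriddedFlowField, path) -> None:
    """Write a gridded field as classic NetCDF (scipy backend)."""
    field.to_dataset().to_netcdf(path, engine="scipy")
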