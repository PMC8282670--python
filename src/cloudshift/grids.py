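"""Gridded containers shared by every pipeline stage.

All grids live on a regular geographic lat-lon raster with cell-center
registration; row 0 is the northernmost row, so ``lat`` is strictly
decreasing and ``lon`` strictly increasing. Missing cells are NaN in float
layers. NetCDF round-trips use xarray (NETCDF3 via the scipy engine), with
one variable per land-cover class or per monthly layer and CF-style
``lat``/``lon`` coordinate variables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

__all__ = [
    "AggregatedDeltaMap",
    "CloudGrid",
    "DeltaMap",
    "ElevationGrid",
    "FractionGrid",
    "MaskReason",
    "TopoStats",
    "geo_axes",
]

_NC_KW = dict(engine="scipy", format="NETCDF3_64BIT")


def geo_axes(n_rows: int, n_cols: int, cell_size: float,
             origin_lat: float, origin_lon: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center lat/lon axes from a north-west grid origin."""
    lat = origin_lat - (np.arange(n_rows) + 0.5) * cell_size
    lon = origin_lon + (np.arange(n_cols) + 0.5) * cell_size
    return lat, lon


class MaskReason(enum.IntEnum):
    """Why a delta-map cell carries no estimate."""

    OK = 0
    EDGE = 1                 # moving window would leave the grid
    TOO_FEW_VALID = 2        # < 60% valid pixels in the window
    TOO_FEW_DISTINCT = 3     # < 40% distinct compositions among valid pixels
    DEGENERATE = 4           # centered design has rank 0 or singular normal eqs
    LOW_DOF = 5              # n <= z + 1, no residual degrees of freedom
    COOCCURRENCE = 6         # I_c below threshold
    TOPOGRAPHY = 7           # v1/v2/v3 rule failed


def _check_axes(lat: np.ndarray, lon: np.ndarray) -> None:
    if lat.ndim != 1 or lon.ndim != 1:
        raise ValueError("lat and lon must be 1-D cell-center axes")
    if lat.size > 1 and not np.all(np.diff(lat) < 0):
        raise ValueError("lat must be strictly decreasing (row 0 = north)")
    if lon.size > 1 and not np.all(np.diff(lon) > 0):
        raise ValueError("lon must be strictly increasing")


@dataclass
class FractionGrid:
    """Per-cell land-cover class fractions (the compositional predictors)."""

    fractions: np.ndarray          # (n_classes, n_lat, n_lon), each in [0, 1]
    class_names: tuple[str, ...]
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.class_names = tuple(self.class_names)
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.lon = np.asarray(self.lon, dtype=np.float64)
        if len(self.class_names) != len(set(self.class_names)):
            raise ValueError("class names must be unique")
        if self.fractions.shape != (len(self.class_names), self.lat.size, self.lon.size):
            raise ValueError("fractions shape must be (n_classes, n_lat, n_lon)")
        _check_axes(self.lat, self.lon)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape[1:]

    @property
    def cell_size(self) -> float:
        return float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else float("nan")

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown land-cover class {name!r}") from None

    def layer(self, name: str) -> np.ndarray:
        return self.fractions[self.class_index(name)]

    def validate_closure(self, atol: float = 1e-6) -> None:
        """Raise if any observed cell's class fractions do not sum to 1."""
        total = self.fractions.sum(axis=0)
        observed = ~np.isnan(total)
        if not np.allclose(total[observed], 1.0, atol=atol):
            worst = np.nanmax(np.abs(total[observed] - 1.0))
            raise ValueError(f"fractions violate closure (max |sum-1| = {worst:.2e})")

    def to_dataset(self) -> xr.Dataset:
        data = {f"frac_{name}": (("lat", "lon"), self.fractions[k])
                for k, name in enumerate(self.class_names)}
        ds = xr.Dataset(data, coords={"lat": self.lat, "lon": self.lon})
        ds.attrs["class_names"] = ",".join(self.class_names)
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "FractionGrid":
        names = tuple(ds.attrs["class_names"].split(","))
        stack = np.stack([ds[f"frac_{n}"].values for n in names])
        return cls(stack, names, ds["lat"].values, ds["lon"].values)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)

    @classmethod
    def open(cls, path) -> "FractionGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class CloudGrid:
    """12 monthly multi-annual mean cloud-fraction layers."""

    clouds: np.ndarray             # (12, n_lat, n_lon), values in [0, 1] or NaN
    lat: np.ndarray
    lon: np.ndarray
    period: str = ""

    def __post_init__(self) -> None:
        self.clouds = np.asarray(self.clouds, dtype=np.float64)
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.lon = np.asarray(self.lon, dtype=np.float64)
        if self.clouds.shape != (12, self.lat.size, self.lon.size):
            raise ValueError("clouds must have shape (12, n_lat, n_lon)")
        _check_axes(self.lat, self.lon)
        finite = self.clouds[np.isfinite(self.clouds)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("cloud fractions must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.clouds.shape[1:]

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"cfrc": (("month", "lat", "lon"), self.clouds)},
            coords={"month": np.arange(1, 13), "lat": self.lat, "lon": self.lon},
        )
        ds.attrs["period"] = self.period
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "CloudGrid":
        return cls(ds["cfrc"].values, ds["lat"].values, ds["lon"].values,
                   ds.attrs.get("period", ""))

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)

    @classmethod
    def open(cls, path) -> "CloudGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class ElevationGrid:
    """Sub-cell elevation statistics: per-cell mean and standard deviation (m)."""

    mean: np.ndarray               # mu_h, metres
    std: np.ndarray                # sigma_h, metres, >= 0
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must share a shape")
        if np.nanmin(self.std, initial=0.0) < 0:
            raise ValueError("sigma_h must be non-negative")
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.lon = np.asarray(self.lon, dtype=np.float64)
        _check_axes(self.lat, self.lon)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"mu_h": (("lat", "lon"), self.mean), "sigma_h": (("lat", "lon"), self.std)},
            coords={"lat": self.lat, "lon": self.lon},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ElevationGrid":
        return cls(ds["mu_h"].values, ds["sigma_h"].values,
                   ds["lat"].values, ds["lon"].values)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)

    @classmethod
    def open(cls, path) -> "ElevationGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class TopoStats:
    """Moving-window orography indicators v1, v2, v3 (metres) per center cell."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    window_size: int = 7

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"v1": (("lat", "lon"), self.v1),
             "v2": (("lat", "lon"), self.v2),
             "v3": (("lat", "lon"), self.v3)},
            coords={"lat": self.lat, "lon": self.lon},
        )
        ds.attrs["window_size"] = self.window_size
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)


@dataclass
class DeltaMap:
    """Per-cell, per-month transition effects with methodological uncertainty.

    ``delta[month, t]`` holds the predicted cloud-fraction change for the
    full land-cover transition ``transitions[t]`` at each window center;
    ``sigma`` its standard deviation; ``reason`` a :class:`MaskReason` code
    explaining every missing cell.
    """

    delta: np.ndarray              # (n_months, n_transitions, n_lat, n_lon)
    sigma: np.ndarray
    reason: np.ndarray             # uint8 MaskReason codes, same shape
    transitions: tuple[tuple[str, str], ...]
    lat: np.ndarray
    lon: np.ndarray
    window_size: int = 7

    def __post_init__(self) -> None:
        if not (self.delta.shape == self.sigma.shape == self.reason.shape):
            raise ValueError("delta, sigma and reason must share a shape")
        present = np.isfinite(self.sigma)
        if present.any() and self.sigma[present].min() < 0:
            raise ValueError("sigma must be non-negative where present")

    @property
    def n_months(self) -> int:
        return self.delta.shape[0]

    def copy(self) -> "DeltaMap":
        return replace(self, delta=self.delta.copy(), sigma=self.sigma.copy(),
                       reason=self.reason.copy())

    def transition_index(self, pair: tuple[str, str]) -> int:
        try:
            return self.transitions.index(pair)
        except ValueError:
            raise KeyError(f"transition {pair} not in map") from None

    def to_dataset(self) -> xr.Dataset:
        labels = [f"{a}->{b}" for a, b in self.transitions]
        ds = xr.Dataset(
            {"delta": (("month", "transition", "lat", "lon"), self.delta),
             "sigma": (("month", "transition", "lat", "lon"), self.sigma),
             "reason_code": (("month", "transition", "lat", "lon"),
                             self.reason.astype(np.int32))},
            coords={"month": np.arange(1, self.delta.shape[0] + 1),
                    "lat": self.lat, "lon": self.lon},
        )
        ds.attrs["transitions"] = ";".join(labels)
        ds.attrs["window_size"] = self.window_size
        ds.attrs["reason_legend"] = ";".join(f"{r.value}={r.name}" for r in MaskReason)
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "DeltaMap":
        transitions = tuple(tuple(lbl.split("->")) for lbl in ds.attrs["transitions"].split(";"))
        return cls(ds["delta"].values, ds["sigma"].values,
                   ds["reason_code"].values.astype(np.uint8),
                   transitions, ds["lat"].values, ds["lon"].values,
                   int(ds.attrs.get("window_size", 7)))

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)

    @classmethod
    def open(cls, path) -> "DeltaMap":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class AggregatedDeltaMap:
    """Block-aggregated transition effects with decorrelated variance.

    One block spans ``block_size`` x ``block_size`` fine cells (0.35 degrees
    for the default 7-cell window at 0.05 degrees); ``support`` is the share
    of fine window centers inside the block that contributed.
    """

    delta: np.ndarray              # (n_months, n_transitions, n_blat, n_blon)
    variance: np.ndarray
    support: np.ndarray
    transitions: tuple[tuple[str, str], ...]
    lat: np.ndarray                # block-center latitudes
    lon: np.ndarray
    block_size: int = 7
    filters_applied: tuple[str, ...] = field(default_factory=tuple)

    def copy(self) -> "AggregatedDeltaMap":
        return replace(self, delta=self.delta.copy(), variance=self.variance.copy(),
                       support=self.support.copy())

    def transition_index(self, pair: tuple[str, str]) -> int:
        try:
            return self.transitions.index(pair)
        except ValueError:
            raise KeyError(f"transition {pair} not in map") from None

    def to_dataset(self) -> xr.Dataset:
        labels = [f"{a}->{b}" for a, b in self.transitions]
        ds = xr.Dataset(
            {"delta": (("month", "transition", "lat", "lon"), self.delta),
             "variance": (("month", "transition", "lat", "lon"), self.variance),
             "support": (("month", "transition", "lat", "lon"), self.support)},
            coords={"month": np.arange(1, self.delta.shape[0] + 1),
                    "lat": self.lat, "lon": self.lon},
        )
        ds.attrs["transitions"] = ";".join(labels)
        ds.attrs["block_size"] = self.block_size
        ds.attrs["filters_applied"] = ";".join(self.filters_applied)
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, **_NC_KW)
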