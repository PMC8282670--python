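"""Synthetic worlds with known planted cloud effects.

Every downstream stage of the pipeline is exercised against data generated
here, where the truth is known by construction: land-cover composition
fields on the unit simplex, cloud fields built as a per-pixel linear
mixture of class-specific cloud responses plus spatially correlated or
white noise, parametric elevation scenarios, multi-year station records
whose cloud fraction depends linearly on the surrounding forest fraction,
and year-by-year series with actual forest-cover change under a climate
drift.

The default world emulates a temperate afforestation frontier: a mosaic
dominated by herbaceous vegetation, deciduous and evergreen forest, with
seven minor classes (shrubland, savanna, wetland, water, bare ground,
snow/ice, urban) at low cover. Noise is added to the cloud response only,
never to the composition, matching the error model the unmixing assumes.
Cloud values are clipped to [0, 1] after noise; clipping biases recovery
near the bounds, so planted responses should stay in the interior
(0.2-0.8).

All generators are deterministic given the configuration seed: a single
global seed fans out to fixed per-operation substreams so that partial
reruns reproduce bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from cloudshift.grids import CloudGrid, ElevationGrid, FractionGrid, geo_axes
from cloudshift.station_validation import StationTable

__all__ = [
    "ClassResponse",
    "WorldConfig",
    "YearlySeries",
    "default_response",
    "generate_cloud_truth",
    "generate_elevation",
    "generate_energy_balance_records",
    "generate_landcover",
    "generate_station_records",
    "generate_yearly_change",
]

#: Analysis legend used throughout: three active vegetation classes plus the
#: minor classes the compositional closure must account for.
DEFAULT_CLASSES: tuple[str, ...] = (
    "herbaceous",
    "deciduous_forest",
    "evergreen_forest",
    "shrubland",
    "savanna",
    "wetland",
    "water",
    "bare",
    "snow_ice",
    "urban",
)

# Fixed substream tags so one world seed reproduces each product independently.
_SUB_LANDCOVER = 101
_SUB_CLOUD = 102
_SUB_ELEVATION = 103
_SUB_STATIONS = 104
_SUB_YEARLY = 105
_SUB_ENERGY = 106


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and texture of a synthetic world.

    ``correlation_length`` is the Gaussian smoothing scale (in cells) of the
    latent fields behind the land-cover mosaic; patches of roughly that size
    guarantee the within-window compositional contrast the space-for-time
    regression needs. ``texture`` adds independent pixel-scale variability
    on top of the patches, emulating the strong cell-to-cell scatter that
    class fractions aggregated from fine categorical maps always carry; it
    keeps every window's regression design well conditioned.
    """

    n_lat: int = 120
    n_lon: int = 120
    cell_size: float = 0.05
    origin_lat: float = 63.0
    origin_lon: float = 10.0
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    correlation_length: float = 4.0
    texture: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 7 or self.n_lon < 7:
            raise ValueError("grid must be at least 7x7 cells (one moving window)")
        if not self.class_names:
            raise ValueError("class_names must be non-empty")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return geo_axes(self.n_lat, self.n_lon, self.cell_size,
                        self.origin_lat, self.origin_lon)


@dataclass
class ClassResponse:
    """True pure-class cloud fractions behind a synthetic cloud field.

    ``beta`` maps each class to its pure-pixel cloud fraction, either one
    scalar or 12 monthly values; ``noise_sd`` is the standard deviation of
    the white observation noise added to the mixed response.
    """

    beta: Mapping[str, float | Sequence[float]]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, value in self.beta.items():
            arr = np.atleast_1d(np.asarray(value, dtype=float))
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"beta for {name!r} must lie in [0, 1]")

    def monthly_matrix(self, class_names: Sequence[str]) -> np.ndarray:
        """(12, n_classes) matrix of betas, scalars broadcast to all months."""
        missing = [c for c in class_names if c not in self.beta]
        if missing:
            raise ValueError(f"response does not cover classes: {missing}")
        cols = []
        for name in class_names:
            arr = np.atleast_1d(np.asarray(self.beta[name], dtype=float))
            if arr.size == 1:
                arr = np.repeat(arr, 12)
            elif arr.size != 12:
                raise ValueError(f"beta for {name!r} must be scalar or 12 monthly values")
            cols.append(arr)
        return np.stack(cols, axis=1)

    def delta(self, from_class: str, to_class: str) -> np.ndarray:
        """True transition effect per month (to_class minus from_class)."""
        idx = [from_class, to_class]
        m = self.monthly_matrix(idx)
        return m[:, 1] - m[:, 0]


def default_response(class_names: Sequence[str] = DEFAULT_CLASSES,
                     herbaceous_beta: float = 0.40,
                     forest_delta: float = 0.05,
                     noise_sd: float = 0.0) -> ClassResponse:
    """A planted response with a known herbaceous-to-forest cloud effect.

    Herbaceous vegetation gets ``herbaceous_beta``; both forest types get
    ``herbaceous_beta + forest_delta``; minor classes get distinct interior
    values so no two classes are confounded.
    """
    minor = {"shrubland": 0.35, "savanna": 0.30, "wetland": 0.55, "water": 0.60,
             "bare": 0.25, "snow_ice": 0.50, "urban": 0.30}
    beta: dict[str, float] = {}
    for name in class_names:
        if name == "herbaceous":
            beta[name] = herbaceous_beta
        elif name in ("deciduous_forest", "evergreen_forest"):
            beta[name] = herbaceous_beta + forest_delta
        else:
            beta[name] = minor.get(name, 0.3)
    return ClassResponse(beta=beta, noise_sd=noise_sd)


def _rng(config_seed: int, substream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, substream])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    raw = rng.standard_normal(shape)
    if length > 0:
        raw = gaussian_filter(raw, sigma=length, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


# Log-scale mean abundance and texture amplitude of each class in the mosaic.
# The transition classes dominate so that herbaceous and forest genuinely
# co-occur within moving windows, as the method requires.
_CLASS_MEAN = {"herbaceous": 1.3, "deciduous_forest": 0.7, "evergreen_forest": 0.7}
_CLASS_AMP = {"herbaceous": 1.6, "deciduous_forest": 1.6, "evergreen_forest": 1.6}
_MINOR_MEAN = -2.6
_MINOR_AMP = 0.9


def generate_landcover(config: WorldConfig) -> FractionGrid:
    """Compositional land-cover mosaic on the unit simplex.

    One smoothed positive latent field per class, normalised per cell, which
    guarantees closure exactly (up to rounding) and gives every class a
    spatially autocorrelated patch structure.
    """
    rng = _rng(config.seed, _SUB_LANDCOVER)
    shape = (config.n_lat, config.n_lon)
    logits = np.empty((len(config.class_names),) + shape)
    for k, name in enumerate(config.class_names):
        mean = _CLASS_MEAN.get(name, _MINOR_MEAN) if len(config.class_names) > 1 else 0.0
        amp = _CLASS_AMP.get(name, _MINOR_AMP)
        logits[k] = (mean + amp * _smooth_field(rng, shape, config.correlation_length)
                     + config.texture * rng.standard_normal(shape))
    weights = np.exp(logits)
    fractions = weights / weights.sum(axis=0, keepdims=True)
    lat, lon = config.axes()
    return FractionGrid(fractions, config.class_names, lat, lon)


def generate_cloud_truth(fractions: FractionGrid, response: ClassResponse,
                         seed: int,
                         noise_correlation_length: float = 0.0) -> CloudGrid:
    """Cloud field as the linear mixture of pure-class responses plus noise.

    Per month ``t`` and cell ``i``: ``y_ti = sum_j beta_tj x_ij + eps`` with
    ``eps ~ N(0, noise_sd)`` independent across cells and months, clipped to
    [0, 1]. A positive ``noise_correlation_length`` (cells) smooths the
    noise field spatially instead, rescaled so its marginal standard
    deviation stays ``noise_sd``.
    """
    betas = response.monthly_matrix(fractions.class_names)        # (12, m)
    clean = np.tensordot(betas, fractions.fractions, axes=(1, 0))  # (12, H, W)
    if response.noise_sd > 0:
        rng = _rng(seed, _SUB_CLOUD)
        noise = rng.standard_normal(clean.shape)
        if noise_correlation_length > 0:
            noise = gaussian_filter(noise, sigma=(0, noise_correlation_length,
                                                  noise_correlation_length),
                                    mode="reflect")
            noise /= noise.std()
        clean = clean + response.noise_sd * noise
    return CloudGrid(np.clip(clean, 0.0, 1.0), fractions.lat, fractions.lon,
                     period="synthetic")


def generate_elevation(config: WorldConfig, scenario: str = "flat") -> ElevationGrid:
    """Parametric elevation scenarios.

    ``flat``: constant 200 m, zero sub-cell relief; ``ridge``: a meridional
    mountain band crossing the grid center (peak ~1500 m, sub-cell sigma up
    to 250 m); ``random_hills``: smoothed random topography.
    """
    shape = (config.n_lat, config.n_lon)
    lat, lon = config.axes()
    if scenario == "flat":
        mean = np.full(shape, 200.0)
        std = np.zeros(shape)
    elif scenario == "ridge":
        cols = np.arange(config.n_lon, dtype=float)
        center = (config.n_lon - 1) / 2.0
        width = max(2.0, config.n_lon / 12.0)
        profile = np.exp(-0.5 * ((cols - center) / width) ** 2)
        mean = 200.0 + 1300.0 * profile[None, :] * np.ones(shape)
        std = 250.0 * profile[None, :] * np.ones(shape)
    elif scenario == "random_hills":
        rng = _rng(config.seed, _SUB_ELEVATION)
        f1 = _smooth_field(rng, shape, config.correlation_length * 2)
        f2 = _smooth_field(rng, shape, config.correlation_length)
        mean = 500.0 + 400.0 * f1
        std = 80.0 * np.abs(f2)
    else:
        raise ValueError(f"unknown elevation scenario {scenario!r}")
    return ElevationGrid(mean, std, lat, lon)


def _station_positions(config: WorldConfig, n_stations: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Paired-network station layout.

    Stations come in couples 40-90 km apart — inside the 30-100 km band the
    pairing stage accepts — while couples sit on a jittered ~220 km lattice
    so that no cross-couple distance falls under 100 km. This emulates the
    sparse validation network the pairing rules aim at: each accepted pair
    is statistically independent of the others.
    """
    lat0 = config.origin_lat - config.n_lat * config.cell_size / 2.0
    n_couples = (n_stations + 1) // 2
    n_cols = max(2, int(np.ceil(np.sqrt(n_couples))))
    spacing_km = 220.0
    dlat = spacing_km / 111.195
    dlon = spacing_km / (111.195 * max(np.cos(np.radians(lat0)), 0.2))
    rows, cols = np.divmod(np.arange(n_couples), n_cols)
    c_lat = lat0 + (rows - rows.mean()) * dlat + rng.uniform(-0.1, 0.1, n_couples)
    c_lon = config.origin_lon + (cols - cols.mean()) * dlon \
        + rng.uniform(-0.1, 0.1, n_couples)
    dist = rng.uniform(40.0, 90.0, n_couples)
    bearing = rng.uniform(0.0, 2 * np.pi, n_couples)
    p_lat = c_lat + dist * np.cos(bearing) / 111.195
    p_lon = c_lon + dist * np.sin(bearing) / (111.195 * np.cos(np.radians(c_lat)))
    lats = np.empty(2 * n_couples)
    lons = np.empty(2 * n_couples)
    lats[0::2], lats[1::2] = c_lat, p_lat
    lons[0::2], lons[1::2] = c_lon, p_lon
    return lats[:n_stations], lons[:n_stations]


def generate_station_records(config: WorldConfig, n_stations: int = 60,
                             years: int = 7, slope: float = 0.05,
                             base: float = 0.4, noise_sd: float = 0.15,
                             station_offset_sd: float = 0.01,
                             hours: Sequence[int] = (8, 14, 20),
                             start_year: int = 2004,
                             seed: int | None = None) -> StationTable:
    """Ground-station records whose cloud cover tracks surrounding forest.

    Each station i draws a 15 km-context forest fraction f_i ~ U(0, 1); its
    records are daily at the given hours with value ``base + slope*f_i``
    plus white per-record noise of standard deviation ``noise_sd``
    (day-to-day weather and observer variability) and a small persistent
    micro-climate offset ~ N(0, station_offset_sd), clipped to [0, 1]. The
    offset is kept small by default because the water and orography filters
    of the validation stage exist precisely to remove stations with strong
    persistent local drivers. Context fractions (forest, water) and the
    orography indicators are attached as truth: water 0 and flat terrain,
    so the default world passes the validation filters.
    """
    if n_stations < 2:
        raise ValueError("need at least 2 stations")
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = _rng(config.seed if seed is None else seed, _SUB_STATIONS)
    lats, lons = _station_positions(config, n_stations, rng)
    forest = rng.uniform(0.0, 1.0, n_stations)
    offset = rng.normal(0.0, station_offset_sd, n_stations)
    station_value = base + slope * forest + offset

    stations = pd.DataFrame({
        "station_id": np.arange(n_stations),
        "lat": lats, "lon": lons,
        "forest_fraction": forest,
        "water_fraction": np.zeros(n_stations),
        "v1": np.zeros(n_stations), "v2": np.zeros(n_stations),
        "v3": np.zeros(n_stations),
    })

    dates = pd.date_range(f"{start_year}-01-01", periods=years * 365, freq="D")
    hours_arr = np.asarray(list(hours), dtype=int)
    n_per_station = dates.size * hours_arr.size
    rec_dates = np.tile(np.repeat(dates.values, hours_arr.size), n_stations)
    rec_hours = np.tile(hours_arr, dates.size * n_stations)
    rec_station = np.repeat(np.arange(n_stations), n_per_station)
    noise = rng.normal(0.0, noise_sd, rec_station.size) if noise_sd > 0 \
        else np.zeros(rec_station.size)
    cfrc = np.clip(station_value[rec_station] + noise, 0.0, 1.0)
    records = pd.DataFrame({
        "station_id": rec_station,
        "date": rec_dates,
        "hour": rec_hours,
        "cfrc": cfrc,
    })
    return StationTable(stations=stations, records=records)


@dataclass
class YearlySeries:
    """Per-year composition and cloud grids with known planted change."""

    fractions: list[FractionGrid]
    clouds: list[CloudGrid]
    changed_mask: np.ndarray        # cells whose forest fraction grows
    true_effect: float              # cloud change per unit forest-fraction change
    climate_drift: float            # uniform cloud offset added per year step
    forest_class: str = "deciduous_forest"
    source_class: str = "herbaceous"


def generate_yearly_change(config: WorldConfig, years: int = 6,
                           change_fraction: float = 0.05,
                           effect: float = 0.05,
                           climate_drift: float = 0.0,
                           df_change: float = 0.5,
                           response: ClassResponse | None = None,
                           noise_sd: float = 0.0,
                           seed: int | None = None) -> YearlySeries:
    """Year-by-year series where some cells actually gain forest.

    A random ``change_fraction`` of cells (among those with enough
    herbaceous cover to convert) ramp ``df_change`` of fractional cover from
    herbaceous to deciduous forest linearly over the years. The cloud field
    for year t is the base mixture plus ``effect`` times the accumulated
    forest gain at changed cells, plus ``t * climate_drift`` everywhere (so
    consecutive years differ by exactly the drift where nothing changed),
    plus optional white noise.
    """
    if years < 2:
        raise ValueError("need at least 2 years")
    if not 0.0 <= change_fraction <= 1.0:
        raise ValueError("change_fraction must lie in [0, 1]")
    base = generate_landcover(config)
    if response is None:
        response = default_response(config.class_names)
    rng = _rng(config.seed if seed is None else seed, _SUB_YEARLY)

    i_src = base.class_index("herbaceous")
    i_dst = base.class_index("deciduous_forest")
    eligible = base.fractions[i_src] >= df_change
    n_change = int(round(change_fraction * eligible.sum()))
    idx = np.flatnonzero(eligible.ravel())
    chosen = rng.choice(idx, size=min(n_change, idx.size), replace=False)
    changed = np.zeros(base.shape, dtype=bool)
    changed.ravel()[chosen] = True

    betas = response.monthly_matrix(base.class_names)
    base_cloud = np.tensordot(betas, base.fractions, axes=(1, 0))

    fractions_by_year: list[FractionGrid] = []
    clouds_by_year: list[CloudGrid] = []
    for t in range(years):
        moved = df_change * t / (years - 1)
        frac = base.fractions.copy()
        frac[i_src][changed] -= moved
        frac[i_dst][changed] += moved
        fractions_by_year.append(FractionGrid(frac, base.class_names, base.lat, base.lon))

        cloud = base_cloud + t * climate_drift
        cloud = cloud + np.where(changed, effect * moved, 0.0)[None, :, :]
        if noise_sd > 0:
            cloud = cloud + rng.normal(0.0, noise_sd, size=cloud.shape)
        clouds_by_year.append(CloudGrid(np.clip(cloud, 0.0, 1.0), base.lat, base.lon,
                                        period=f"year{t}"))
    return YearlySeries(fractions_by_year, clouds_by_year, changed, effect,
                        climate_drift)


def generate_energy_balance_records(n: int = 5000, seed: int = 0,
                                    snow_share: float = 0.15) -> pd.DataFrame:
    """Synthetic per-block surface-energy-balance changes for afforestation.

    Emulates the joint behaviour the binning diagnostic displays: cloud
    change grows with the net-radiation change and with the turbulent-flux
    changes; a snow stratum (strong albedo drop, Delta alpha < -0.15)
    behaves differently. Columns: d_cfrc, d_rn, d_le, d_hg, d_alpha (W m-2
    for fluxes, unitless otherwise).
    """
    rng = _rng(seed, _SUB_ENERGY)
    snow = rng.uniform(size=n) < snow_share
    d_rn = rng.normal(8.0, 5.0, n) + np.where(snow, -12.0, 0.0)
    d_le = rng.normal(5.0, 4.0, n)
    d_hg = d_rn - d_le + rng.normal(0.0, 2.0, n)
    d_alpha = np.where(snow, rng.normal(-0.25, 0.04, n), rng.normal(-0.03, 0.03, n))
    d_cfrc = (0.0015 * d_rn + 0.0010 * d_le + 0.0005 * d_hg
              + np.where(snow, -0.02, 0.0) + rng.normal(0.0, 0.01, n))
    return pd.DataFrame({"d_cfrc": d_cfrc, "d_rn": d_rn, "d_le": d_le,
                         "d_hg": d_hg, "d_alpha": d_alpha})
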