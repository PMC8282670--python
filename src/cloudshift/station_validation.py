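"""Ground-based confirmation of the satellite afforestation signal.

Synoptic weather stations report cloud cover by eye at fixed sub-daily
hours. Stations are given a land-cover context (forest and water fraction
within a 15 km region of influence), filtered for water, orography and
record length, then grouped into pairs 30-100 km apart: close enough to
share the large-scale weather, far enough that their regions of influence
do not overlap. Within each pair the per-(month, hour) difference in mean
cloud fraction is paired with the difference in forest fraction, and a
regression forced through the origin extrapolates the slope to a full
no-forest -> forest transition, directly comparable with the satellite
estimate of the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cloudshift.grids import AggregatedDeltaMap, FractionGrid, TopoStats

__all__ = [
    "StationTable",
    "attach_station_context",
    "compare_with_satellite",
    "filter_stations",
    "haversine_km",
    "octas_to_fraction",
    "origin_regression",
    "pair_stations",
    "pairwise_deltas",
    "slope_matrix",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class StationTable:
    """Stations plus their raw records.

    ``stations``: one row per station with station_id, lat, lon and (once
    attached) context columns forest_fraction, water_fraction, v1, v2, v3.
    ``records``: long table with station_id, date, hour, cfrc in [0, 1].
    """

    stations: pd.DataFrame
    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"station_id", "lat", "lon"}
        if not need.issubset(self.stations.columns):
            raise ValueError(f"stations table needs columns {sorted(need)}")
        need = {"station_id", "date", "hour", "cfrc"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"records table needs columns {sorted(need)}")
        cfrc = self.records["cfrc"].to_numpy()
        if cfrc.size and (np.nanmin(cfrc) < 0 or np.nanmax(cfrc) > 1):
            raise ValueError("cfrc must lie in [0, 1]")

    def n_records(self) -> pd.Series:
        return self.records.groupby("station_id").size()

    def write_csv(self, stations_path, records_path) -> None:
        self.stations.to_csv(stations_path, index=False)
        rec = self.records.copy()
        rec["date"] = pd.to_datetime(rec["date"]).dt.strftime("%Y-%m-%d")
        rec.to_csv(records_path, index=False)

    @classmethod
    def read_csv(cls, stations_path, records_path) -> "StationTable":
        stations = pd.read_csv(stations_path)
        records = pd.read_csv(records_path, parse_dates=["date"])
        return cls(stations=stations, records=records)


def octas_to_fraction(records: pd.DataFrame, column: str = "octa") -> pd.DataFrame:
    """Convert okta-coded cloud cover (0-8) to fractions; drop code 9.

    Code 9 means the sky was obscured (typically fog) and carries no cloud
    fraction information, so those records are removed rather than imputed.
    """
    out = records[records[column] != 9].copy()
    out["cfrc"] = out[column] / 8.0
    return out.drop(columns=[column])


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a spherical earth (km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _context_fraction(layer: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                      st_lat: float, st_lon: float, radius_km: float) -> float:
    """Area-weighted mean of a fraction layer over cells within the radius."""
    dlat_km = np.abs(lat - st_lat) * 111.195
    near_rows = np.flatnonzero(dlat_km <= radius_km * 1.5)
    if near_rows.size == 0:
        return np.nan
    sub_lat = lat[near_rows]
    dist = haversine_km(sub_lat[:, None], lon[None, :], st_lat, st_lon)
    inside = dist <= radius_km
    if not inside.any():
        return np.nan
    weights = np.cos(np.radians(sub_lat))[:, None] * np.ones_like(dist)
    vals = layer[near_rows, :]
    ok = inside & np.isfinite(vals)
    if not ok.any():
        return np.nan
    return float(np.sum(vals[ok] * weights[ok]) / np.sum(weights[ok]))


def attach_station_context(table: StationTable, fractions: FractionGrid,
                           topo: TopoStats | None = None,
                           forest_classes: tuple[str, ...] = ("deciduous_forest",
                                                              "evergreen_forest"),
                           water_class: str = "water",
                           radius_km: float = 15.0) -> StationTable:
    """Attach 15 km-context forest/water fractions and orography indicators.

    Fractions are area-weighted means over map cells whose centers fall
    within ``radius_km`` of the station; orography indicators are sampled at
    the nearest cell. Stations outside the map (no cell within the radius)
    are excluded.
    """
    forest_layer = np.sum([fractions.layer(c) for c in forest_classes
                           if c in fractions.class_names], axis=0)
    water_layer = (fractions.layer(water_class)
                   if water_class in fractions.class_names
                   else np.zeros(fractions.shape))
    rows = []
    for _, st in table.stations.iterrows():
        f = _context_fraction(forest_layer, fractions.lat, fractions.lon,
                              st["lat"], st["lon"], radius_km)
        w = _context_fraction(water_layer, fractions.lat, fractions.lon,
                              st["lat"], st["lon"], radius_km)
        if np.isnan(f):
            continue                          # outside map coverage
        row = dict(st)
        row["forest_fraction"] = f
        row["water_fraction"] = w
        if topo is not None:
            i = int(np.argmin(np.abs(topo.lat - st["lat"])))
            j = int(np.argmin(np.abs(topo.lon - st["lon"])))
            row["v1"], row["v2"], row["v3"] = (topo.v1[i, j], topo.v2[i, j],
                                               topo.v3[i, j])
        rows.append(row)
    stations = pd.DataFrame(rows).reset_index(drop=True)
    kept = set(stations["station_id"])
    records = table.records[table.records["station_id"].isin(kept)].reset_index(drop=True)
    return StationTable(stations=stations, records=records)


def filter_stations(table: StationTable, max_water: float = 0.05,
                    min_records: int = 2555,
                    v1_max: float = 50.0, v2_max: float = 100.0,
                    v3_max: float = 100.0) -> StationTable:
    """Drop stations dominated by water, rough terrain or sparse records.

    ``min_records`` defaults to roughly seven years of daily reports; the
    orography rule is the same v1/v2/v3 criterion used to mask the
    satellite analysis.
    """
    st = table.stations
    counts = table.n_records().reindex(st["station_id"]).fillna(0).to_numpy()
    keep = (st["water_fraction"].to_numpy() <= max_water) & (counts >= min_records)
    for col, bound in (("v1", v1_max), ("v2", v2_max), ("v3", v3_max)):
        if col in st.columns:
            keep &= st[col].to_numpy() < bound
    stations = st[keep].reset_index(drop=True)
    kept = set(stations["station_id"])
    records = table.records[table.records["station_id"].isin(kept)].reset_index(drop=True)
    return StationTable(stations=stations, records=records)


def pair_stations(stations: pd.DataFrame, min_km: float = 30.0,
                  max_km: float = 100.0) -> pd.DataFrame:
    """All unordered station pairs with great-circle distance in [min, max] km.

    A station may belong to several pairs. Columns: pair_id, station_a,
    station_b, distance_km, dx (forest fraction b minus a, if context is
    attached), centroid_lat, centroid_lon.
    """
    if len(stations) < 2:
        raise ValueError("need at least 2 stations to pair")
    lat = stations["lat"].to_numpy()
    lon = stations["lon"].to_numpy()
    ids = stations["station_id"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    ii, jj = np.triu_indices(len(stations), k=1)
    ok = (d[ii, jj] >= min_km) & (d[ii, jj] <= max_km)
    ii, jj = ii[ok], jj[ok]
    pairs = pd.DataFrame({
        "pair_id": np.arange(ii.size),
        "station_a": ids[ii], "station_b": ids[jj],
        "distance_km": d[ii, jj],
        "centroid_lat": (lat[ii] + lat[jj]) / 2.0,
        "centroid_lon": (lon[ii] + lon[jj]) / 2.0,
    })
    if "forest_fraction" in stations.columns:
        forest = stations.set_index("station_id")["forest_fraction"]
        pairs["dx"] = forest.loc[pairs["station_b"]].to_numpy() \
            - forest.loc[pairs["station_a"]].to_numpy()
    return pairs


def pairwise_deltas(pairs: pd.DataFrame, table: StationTable) -> pd.DataFrame:
    """Per-pair, per-(month, hour) cloud and forest differences.

    ``dy`` is the mean cloud fraction at station B minus station A within
    the bin; bins where either station has no record are omitted. ``dx``
    keeps the same station orientation as ``dy``.
    """
    rec = table.records
    month = pd.to_datetime(rec["date"]).dt.month
    means = (rec.assign(month=month)
             .groupby(["station_id", "month", "hour"])["cfrc"]
             .mean().rename("mean_cfrc").reset_index())
    out = []
    for _, pr in pairs.iterrows():
        a = means[means["station_id"] == pr["station_a"]]
        b = means[means["station_id"] == pr["station_b"]]
        merged = a.merge(b, on=["month", "hour"], suffixes=("_a", "_b"))
        if merged.empty:
            continue
        out.append(pd.DataFrame({
            "pair_id": int(pr["pair_id"]),
            "month": merged["month"], "hour": merged["hour"],
            "dy": merged["mean_cfrc_b"].to_numpy() - merged["mean_cfrc_a"].to_numpy(),
            "dx": pr["dx"],
        }))
    if not out:
        return pd.DataFrame(columns=["pair_id", "month", "hour", "dy", "dx"])
    return pd.concat(out, ignore_index=True)


def origin_regression(dx: np.ndarray, dy: np.ndarray) -> tuple[float, float, bool, int]:
    """Forced-origin slope of dy on dx with its standard error.

    slope = sum(dx*dy) / sum(dx^2); SE = sqrt(sum(r^2) / ((k-1) * sum(dx^2)))
    over k pairs; the slope is flagged significant when |slope| > 2 SE.
    Returns (slope, se, significant, k); raises if every dx is zero.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    ok = np.isfinite(dx) & np.isfinite(dy)
    dx, dy = dx[ok], dy[ok]
    sxx = float(np.sum(dx * dx))
    if dx.size == 0 or sxx == 0.0:
        raise ValueError("origin regression undefined: no nonzero dx")
    slope = float(np.sum(dx * dy)) / sxx
    k = dx.size
    if k > 1:
        rss = float(np.sum((dy - slope * dx) ** 2))
        se = float(np.sqrt(rss / ((k - 1) * sxx)))
    else:
        se = float("nan")
    significant = bool(np.isfinite(se) and abs(slope) > 2 * se)
    return slope, se, significant, k


def slope_matrix(deltas: pd.DataFrame) -> pd.DataFrame:
    """Forced-origin slope per (month, hour) bin.

    Columns: month, hour, slope, se, significant, n_pairs. Bins where the
    regression is undefined (all dx zero) are omitted.
    """
    rows = []
    for (m, h), grp in deltas.groupby(["month", "hour"]):
        try:
            slope, se, sig, k = origin_regression(grp["dx"].to_numpy(),
                                                  grp["dy"].to_numpy())
        except ValueError:
            continue
        rows.append({"month": int(m), "hour": int(h), "slope": slope,
                     "se": se, "significant": sig, "n_pairs": k})
    return pd.DataFrame(rows)


def compare_with_satellite(pairs: pd.DataFrame, deltas: pd.DataFrame,
                           satellite: AggregatedDeltaMap,
                           transition: tuple[str, str] | int = 0,
                           hour: int = 14,
                           buffer_km: float = 50.0) -> pd.DataFrame:
    """Monthly ground slope at one hour vs nearby satellite transition effect.

    For each month: the forced-origin slope over the pairs at ``hour``
    (closest to the satellite overpass), against the average of satellite
    block estimates lying within ``buffer_km`` of each pair centroid
    (pooled over pairs, with duplicates when buffers overlap, so every
    pair's neighbourhood counts once per pair).
    """
    t = satellite.transition_index(transition) if isinstance(transition, tuple) \
        else int(transition)
    blat, blon = satellite.lat, satellite.lon
    glat = np.repeat(blat, blon.size)
    glon = np.tile(blon, blat.size)
    per_pair_blocks = {}
    for _, pr in pairs.iterrows():
        dist = haversine_km(glat, glon, pr["centroid_lat"], pr["centroid_lon"])
        per_pair_blocks[int(pr["pair_id"])] = np.flatnonzero(dist <= buffer_km)
    if all(idx.size == 0 for idx in per_pair_blocks.values()):
        raise ValueError("no satellite blocks within the buffer of any pair")

    rows = []
    at_hour = deltas[deltas["hour"] == hour]
    for m in range(1, satellite.delta.shape[0] + 1):
        grp = at_hour[at_hour["month"] == m]
        try:
            slope, se, sig, k = origin_regression(grp["dx"].to_numpy(),
                                                  grp["dy"].to_numpy())
        except ValueError:
            continue
        layer = satellite.delta[m - 1, t].ravel()
        sat_vals = np.concatenate([layer[idx] for idx in per_pair_blocks.values()
                                   if idx.size]) if per_pair_blocks else np.array([])
        sat_vals = sat_vals[np.isfinite(sat_vals)]
        rows.append({
            "month": m, "ground_slope": slope, "ground_se": se,
            "ground_significant": sig, "n_pairs": k,
            "satellite_mean": float(sat_vals.mean()) if sat_vals.size else np.nan,
            "satellite_se": (float(sat_vals.std(ddof=1) / np.sqrt(sat_vals.size))
                             if sat_vals.size > 1 else np.nan),
            "n_satellite_cells": int(sat_vals.size),
        })
    return pd.DataFrame(rows)
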