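"""Convert raw inputs into analysis-ready grids.

Three preparation steps feed the pipeline: a fine categorical land-cover
map is aggregated spatially (pixel counting per coarse block) and
thematically (a legend maps fine codes to analysis classes) into class
fraction layers; daily cloud series are reduced to a 12-layer monthly
climatology (daily -> per-(year, month) mean -> across-years mean, so every
year weighs equally regardless of daily coverage); and sub-cell elevation
statistics are summarised per moving window into the three orography
indicators used for masking:

    v1 = mean of sigma_h over the window,
    v2 = |mu_h(center) - mean of mu_h over the window|,
    v3 = |sigma_h(center) - v1|.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from cloudshift.grids import CloudGrid, ElevationGrid, FractionGrid, TopoStats, geo_axes

__all__ = [
    "aggregate_landcover_classes",
    "elevation_window_stats",
    "monthly_cloud_climatology",
]


def aggregate_landcover_classes(classmap: np.ndarray, legend: Mapping[int, str],
                                factor: int,
                                class_names: Sequence[str] | None = None,
                                missing_value: int | None = None,
                                max_missing_share: float = 0.5,
                                fine_cell_size: float = 0.005,
                                origin_lat: float = 0.0,
                                origin_lon: float = 0.0) -> FractionGrid:
    """Aggregate a fine categorical map to coarse per-class fractions.

    Each coarse cell of ``factor`` x ``factor`` fine pixels gets, for every
    analysis class, the share of its fine pixels whose legend entry maps to
    that class; fractions close to 1 over all classes. Fine pixels equal to
    ``missing_value`` are excluded from the count, and a coarse cell whose
    missing share exceeds ``max_missing_share`` becomes missing entirely
    (fractions from a mostly-unobserved block would be biased).
    """
    classmap = np.asarray(classmap)
    if factor < 1:
        raise ValueError("aggregation factor must be a positive integer")
    if classmap.shape[0] % factor or classmap.shape[1] % factor:
        raise ValueError("coarse resolution must be an integer multiple of "
                         "the fine resolution (map shape not divisible)")
    if class_names is None:
        class_names = tuple(dict.fromkeys(legend.values()))
    class_index = {name: k for k, name in enumerate(class_names)}

    codes = np.unique(classmap)
    if missing_value is not None:
        codes = codes[codes != missing_value]
    unmapped = [int(c) for c in codes if c not in legend]
    if unmapped:
        raise KeyError(f"fine class codes missing from legend: {unmapped}")

    lut_size = int(classmap.max()) + 2 if classmap.size else 1
    lut = np.full(lut_size, -1, dtype=np.int64)
    for code, name in legend.items():
        if 0 <= code < lut_size:
            lut[code] = class_index[name]
    mapped = np.where(classmap == missing_value, -1,
                      lut[np.clip(classmap, 0, lut_size - 1)]) \
        if missing_value is not None else lut[classmap]

    nb_lat = classmap.shape[0] // factor
    nb_lon = classmap.shape[1] // factor
    blocks = mapped.reshape(nb_lat, factor, nb_lon, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nb_lat * nb_lon, factor * factor)

    m = len(class_names)
    counts = np.zeros((nb_lat * nb_lon, m))
    for k in range(m):
        counts[:, k] = (blocks == k).sum(axis=1)
    observed = counts.sum(axis=1)
    fractions = np.full((m, nb_lat * nb_lon), np.nan)
    ok = observed >= (1.0 - max_missing_share) * factor * factor
    fractions[:, ok] = (counts[ok] / observed[ok, None]).T
    fractions = fractions.reshape(m, nb_lat, nb_lon)

    lat, lon = geo_axes(nb_lat, nb_lon, factor * fine_cell_size,
                        origin_lat, origin_lon)
    return FractionGrid(fractions, tuple(class_names), lat, lon)


def monthly_cloud_climatology(dates: Sequence, layers: np.ndarray,
                              lat: np.ndarray, lon: np.ndarray,
                              period: str = "") -> CloudGrid:
    """Multi-annual monthly mean cloud cover from dated daily layers.

    Daily values are first averaged within each (year, month), then the
    per-year monthly means are averaged across years for each of the 12
    calendar months — equal weight per year, however many days each year
    contributed. Cells with no data in any year of a month stay missing.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    layers = np.asarray(layers, dtype=float)
    if dates.size == 0:
        raise ValueError("empty daily series")
    if layers.shape[0] != dates.size:
        raise ValueError("one layer per date required")
    years = dates.astype("datetime64[Y]").astype(int) + 1970
    months = (dates.astype("datetime64[M]").astype(int) % 12) + 1

    shape = layers.shape[1:]
    month_sum = np.zeros((12,) + shape)
    month_cnt = np.zeros((12,) + shape)
    for ym in np.unique(years * 100 + months):
        sel = (years * 100 + months) == ym
        chunk = layers[sel]
        with np.errstate(invalid="ignore"):
            ym_mean = np.nansum(chunk, axis=0)
            n_days = np.isfinite(chunk).sum(axis=0)
        have = n_days > 0
        ym_mean = np.where(have, ym_mean / np.maximum(n_days, 1), np.nan)
        m = int(ym % 100) - 1
        month_sum[m][have] += ym_mean[have]
        month_cnt[m][have] += 1
    clim = np.where(month_cnt > 0, month_sum / np.maximum(month_cnt, 1), np.nan)
    return CloudGrid(np.clip(clim, 0.0, 1.0), lat, lon, period=period)


def elevation_window_stats(elev: ElevationGrid, window_size: int = 7) -> TopoStats:
    """Orography indicators v1, v2, v3 per window center.

    All three are non-negative and zero over flat terrain. Any missing
    elevation inside the window, and any window touching the grid edge,
    makes the center missing.
    """
    h = window_size // 2

    def window_mean(field: np.ndarray) -> np.ndarray:
        # Plain mean over explicit windows: NaN propagates only within its
        # own window (the missing rule), and edge centers stay missing.
        out = np.full(field.shape, np.nan)
        if field.shape[0] >= window_size and field.shape[1] >= window_size:
            view = np.lib.stride_tricks.sliding_window_view(
                field, (window_size, window_size))
            out[h:field.shape[0] - h, h:field.shape[1] - h] = view.mean(axis=(2, 3))
        return out

    v1 = window_mean(elev.std)
    v2 = np.abs(elev.mean - window_mean(elev.mean))
    v3 = np.abs(elev.std - v1)
    return TopoStats(v1, v2, v3, elev.lat, elev.lon, window_size)
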