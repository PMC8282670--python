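"""Alternative effect estimate from actual year-to-year forest change.

Where forest cover really changed between two years, the cloud-cover
difference decomposes as Delta y = Delta y_fcc + Delta y_res: the part
caused by forest-cover change plus a residual from climate variability.
The residual at a pixel is estimated as the mean Delta y over no-change
pixels (|Delta f| below a threshold) in a larger moving window, so a
spatially uniform climate shift cancels exactly. The forest effect is then
normalised to a full 0 -> 1 transition, Delta y_fcc / Delta f, comparable
in sign and magnitude with the space-for-time estimate. All unordered year
pairs contribute, not just first-vs-last, and each month is treated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from cloudshift.grids import CloudGrid, FractionGrid

__all__ = [
    "TemporalDeltas",
    "estimate_residual",
    "forest_change_effect",
    "pairwise_year_deltas",
    "run_temporal_method",
]

DEFAULT_FOREST_CLASSES = ("deciduous_forest", "evergreen_forest")


@dataclass
class TemporalDeltas:
    """Year-pair differences of cloud cover and forest fraction."""

    dy: np.ndarray                 # (n_pairs, 12, n_lat, n_lon)
    df: np.ndarray                 # (n_pairs, n_lat, n_lon)
    year_pairs: tuple[tuple[int, int], ...]
    lat: np.ndarray
    lon: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.dy.shape[0]


def _forest_layer(fractions: FractionGrid,
                  forest_classes: Sequence[str]) -> np.ndarray:
    present = [c for c in forest_classes if c in fractions.class_names]
    if not present:
        raise KeyError(f"none of {forest_classes} in legend")
    return np.sum([fractions.layer(c) for c in present], axis=0)


def pairwise_year_deltas(clouds_by_year: Sequence[CloudGrid],
                         fractions_by_year: Sequence[FractionGrid],
                         forest_classes: Sequence[str] = DEFAULT_FOREST_CLASSES
                         ) -> TemporalDeltas:
    """Differences over all unordered year pairs (t1 < t2).

    dy = y(t2) - y(t1) per month and pixel; df is the same difference of
    the summed forest fraction. With Y years there are Y*(Y-1)/2 pairs.
    """
    n_years = len(clouds_by_year)
    if n_years < 2 or len(fractions_by_year) != n_years:
        raise ValueError("need aligned cloud and fraction grids for >= 2 years")
    ref = clouds_by_year[0]
    forest = np.stack([_forest_layer(f, forest_classes) for f in fractions_by_year])
    pairs = list(combinations(range(n_years), 2))
    dy = np.stack([clouds_by_year[t2].clouds - clouds_by_year[t1].clouds
                   for t1, t2 in pairs])
    df = np.stack([forest[t2] - forest[t1] for t1, t2 in pairs])
    return TemporalDeltas(dy, df, tuple(pairs), ref.lat, ref.lon)


def estimate_residual(dy: np.ndarray, df: np.ndarray, window_size: int = 21,
                      no_change_threshold: float = 0.05,
                      min_reference: int = 10) -> np.ndarray:
    """Climate-variability residual: windowed mean dy over no-change pixels.

    Pixels with |df| < ``no_change_threshold`` (and observed dy) are the
    reference set; the residual at a center is their unweighted mean inside
    the window, missing when fewer than ``min_reference`` are available.
    Windows are clipped at the grid edge (the in-grid part is used).
    """
    ref = (np.abs(df) < no_change_threshold) & np.isfinite(dy)
    w2 = window_size * window_size
    vals = np.where(ref, dy, 0.0)
    total = uniform_filter(vals, size=window_size, mode="constant", cval=0.0) * w2
    count = uniform_filter(ref.astype(float), size=window_size,
                           mode="constant", cval=0.0) * w2
    count = np.rint(count)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = total / count
    res[count < min_reference] = np.nan
    return res


def forest_change_effect(dy: np.ndarray, dy_res: np.ndarray, df: np.ndarray,
                         min_change: float = 0.1) -> np.ndarray:
    """Normalised full-transition effect: (dy - dy_res) / df.

    Only pixels with |df| >= ``min_change`` and an available residual carry
    an estimate; everything else is missing.
    """
    usable = (np.abs(df) >= min_change) & np.isfinite(dy_res) & np.isfinite(dy)
    out = np.full(dy.shape, np.nan)
    out[usable] = (dy[usable] - dy_res[usable]) / df[usable]
    return out


def run_temporal_method(clouds_by_year: Sequence[CloudGrid],
                        fractions_by_year: Sequence[FractionGrid],
                        forest_classes: Sequence[str] = DEFAULT_FOREST_CLASSES,
                        window_size: int = 21,
                        no_change_threshold: float = 0.05,
                        min_reference: int = 10,
                        min_change: float = 0.1
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Full temporal estimate: per-month effect summary plus effect maps.

    Returns (summary, effects): ``summary`` has one row per month with the
    mean normalised effect over all year pairs and change pixels, its
    standard error and the record count; ``effects`` has shape
    (n_pairs, 12, n_lat, n_lon) with NaN where no estimate exists.
    """
    deltas = pairwise_year_deltas(clouds_by_year, fractions_by_year, forest_classes)
    effects = np.full(deltas.dy.shape, np.nan)
    for p in range(deltas.n_pairs):
        for m in range(12):
            res = estimate_residual(deltas.dy[p, m], deltas.df[p], window_size,
                                    no_change_threshold, min_reference)
            effects[p, m] = forest_change_effect(deltas.dy[p, m], res,
                                                 deltas.df[p], min_change)
    rows = []
    for m in range(12):
        vals = effects[:, m][np.isfinite(effects[:, m])]
        rows.append({
            "month": m + 1,
            "mean_effect": float(vals.mean()) if vals.size else np.nan,
            "se": (float(vals.std(ddof=1) / np.sqrt(vals.size))
                   if vals.size > 1 else np.nan),
            "n_records": int(vals.size),
        })
    return pd.DataFrame(rows), effects
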