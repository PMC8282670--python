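"""Masking, decorrelated aggregation and summary statistics for delta maps.

Raw window estimates are only meaningful where the two transition classes
genuinely co-occur (co-occurrence index I_c >= 0.5), where orography does
not confound the spatial gradient (v1 < 50 m, v2 < 100 m, v3 < 100 m), and
after aggregation to the window's own spatial support. Because neighbouring
moving windows share most of their pixels, their estimates are strongly
autocorrelated: aggregation therefore builds a covariance from pairwise
window-overlap fractions, Sigma_a = D_a R_a D_a^t, and uses the
generalised inverse-variance weights w = Sigma_a^{-1} 1 / (1^t Sigma_a^{-1} 1),
whose aggregated variance is 1 / (1^t Sigma_a^{-1} 1). Outlier filters and
a forest-type merge follow, plus display coarsening and the seasonal
positive-fraction summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cloudshift.grids import (AggregatedDeltaMap, CloudGrid, DeltaMap,
                              FractionGrid, MaskReason, TopoStats)

__all__ = [
    "CooccurrenceGrid",
    "aggregate_blocks",
    "block_presence",
    "coarsen_for_display",
    "cooccurrence_grid",
    "cooccurrence_index",
    "decorrelated_aggregate",
    "filter_aggregates",
    "mask_cooccurrence",
    "mask_topography",
    "merge_forest_types",
    "relative_change",
    "seasonal_positive_fraction",
    "window_overlap_matrix",
]


# --------------------------------------------------------------------------
# co-occurrence

@lru_cache(maxsize=None)
def _reference_points(n: int) -> tuple[np.ndarray, float]:
    """n ideal points evenly spread on the line B = 1 - A, with the distance
    normaliser sum_k ||q_k||."""
    k = np.arange(n, dtype=float)
    q = np.column_stack([(n - 1 - k) / (n - 1), k / (n - 1)]) if n > 1 \
        else np.array([[1.0, 0.0]])
    return q, float(np.sqrt((q ** 2).sum(axis=1)).sum())


def cooccurrence_index(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Index of vegetation co-occurrence for one window.

    Each valid pixel is a point p = (p_A, p_B) in the presence plane; the
    reference points q_k sit evenly along the full-co-occurrence line
    B = 1 - A. I_c = 1 - sum_i min_k ||p_i - q_k|| / sum_k ||q_k||, clipped
    to [0, 1]: 1 when the window realises the ideal balanced gradient, small
    when both classes are nearly absent.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    n = p_a.size
    if n < 2:
        return float("nan")
    q, denom = _reference_points(n)
    d = np.hypot(p_a[:, None] - q[None, :, 0], p_b[:, None] - q[None, :, 1])
    num = d.min(axis=1).sum()
    return float(np.clip(1.0 - num / denom, 0.0, 1.0))


@dataclass
class CooccurrenceGrid:
    """Per-cell I_c for one class pair on the delta map's grid."""

    ic: np.ndarray
    pair: tuple[str, str]
    lat: np.ndarray
    lon: np.ndarray


def cooccurrence_grid(fractions: FractionGrid, class_a: str, class_b: str,
                      window_size: int = 7, water_class: str = "water",
                      water_threshold: float = 0.5) -> CooccurrenceGrid:
    """I_c at every interior window center for the pair (class_a, class_b).

    Uses the same moving window and pixel-validity rule as the unmixing so
    the mask applies to exactly the pixels that were estimated.
    """
    a = fractions.layer(class_a)
    b = fractions.layer(class_b)
    valid = np.isfinite(a) & np.isfinite(b)
    if water_class in fractions.class_names:
        valid &= fractions.layer(water_class) < water_threshold
    h = window_size // 2
    n_lat, n_lon = fractions.shape
    ic = np.full((n_lat, n_lon), np.nan)
    for r in range(h, n_lat - h):
        for c in range(h, n_lon - h):
            sl = (slice(r - h, r + h + 1), slice(c - h, c + h + 1))
            ok = valid[sl].ravel()
            if ok.sum() < 2:
                continue
            ic[r, c] = cooccurrence_index(a[sl].ravel()[ok], b[sl].ravel()[ok])
    return CooccurrenceGrid(ic, (class_a, class_b), fractions.lat, fractions.lon)


def mask_cooccurrence(delta: DeltaMap, coocs: Sequence[CooccurrenceGrid],
                      threshold: float = 0.5) -> DeltaMap:
    """Drop cells whose transition pair lacks co-occurrence (I_c < threshold)."""
    out = delta.copy()
    by_pair: Mapping[tuple[str, str], CooccurrenceGrid] = {g.pair: g for g in coocs}
    for ti, pair in enumerate(delta.transitions):
        grid = by_pair.get(pair) or by_pair.get((pair[1], pair[0]))
        if grid is None:
            raise KeyError(f"no co-occurrence grid for transition {pair}")
        if not (np.array_equal(grid.lat, delta.lat)
                and np.array_equal(grid.lon, delta.lon)):
            raise ValueError("co-occurrence grid not aligned with delta map")
        fail = ~(grid.ic >= threshold)       # NaN counts as failing
        for mi in range(delta.n_months):
            present = np.isfinite(out.delta[mi, ti])
            kill = present & fail
            out.delta[mi, ti][kill] = np.nan
            out.sigma[mi, ti][kill] = np.nan
            out.reason[mi, ti][kill] = MaskReason.COOCCURRENCE
    return out


def mask_topography(delta: DeltaMap, topo: TopoStats, v1_max: float = 50.0,
                    v2_max: float = 100.0, v3_max: float = 100.0) -> DeltaMap:
    """Drop cells over complex terrain: keep only v1 < 50, v2 < 100, v3 < 100 m."""
    if not (np.array_equal(topo.lat, delta.lat)
            and np.array_equal(topo.lon, delta.lon)):
        raise ValueError("topographic stats not aligned with delta map")
    passes = (topo.v1 < v1_max) & (topo.v2 < v2_max) & (topo.v3 < v3_max)
    fail = ~passes                            # NaN indicators fail too
    out = delta.copy()
    for mi in range(delta.n_months):
        for ti in range(len(delta.transitions)):
            present = np.isfinite(out.delta[mi, ti])
            kill = present & fail
            out.delta[mi, ti][kill] = np.nan
            out.sigma[mi, ti][kill] = np.nan
            out.reason[mi, ti][kill] = MaskReason.TOPOGRAPHY
    return out


# --------------------------------------------------------------------------
# decorrelated aggregation

def window_overlap_matrix(rows: np.ndarray, cols: np.ndarray,
                          window_size: int = 7) -> np.ndarray:
    """Pairwise fraction of shared pixels between windows at the given centers.

    Two W x W windows offset by (dr, dc) share
    max(0, W - |dr|) * max(0, W - |dc|) / W^2 of their area.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    w = float(window_size)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    return np.maximum(0.0, w - dr) * np.maximum(0.0, w - dc) / (w * w)


def decorrelated_aggregate(deltas: np.ndarray, sigmas: np.ndarray,
                           overlap: np.ndarray, sigma_floor: float = 1e-6
                           ) -> tuple[float, float, np.ndarray]:
    """Overlap-aware inverse-variance mean of correlated window estimates.

    Builds Sigma_a = D_a R_a D_a^t from the per-center standard deviations
    (floored at ``sigma_floor`` so exact fits cannot produce a singular
    covariance) and returns (weighted mean, aggregated variance, weights)
    with w = Sigma_a^{-1} 1 / (1^t Sigma_a^{-1} 1) and
    var = 1 / (1^t Sigma_a^{-1} 1).
    """
    deltas = np.asarray(deltas, dtype=float)
    sigmas = np.maximum(np.asarray(sigmas, dtype=float), sigma_floor)
    k = deltas.size
    if k == 0:
        raise ValueError("no valid centers to aggregate")
    if k == 1:
        return float(deltas[0]), float(sigmas[0] ** 2), np.ones(1)
    cov = overlap * np.outer(sigmas, sigmas)
    ones = np.ones(k)
    try:
        solved = np.linalg.solve(cov, ones)
    except np.linalg.LinAlgError:
        cov = cov + 1e-12 * cov.diagonal().max() * np.eye(k)
        solved = np.linalg.solve(cov, ones)
    denom = float(ones @ solved)
    w = solved / denom
    return float(w @ deltas), 1.0 / denom, w


def aggregate_blocks(delta: DeltaMap, block_size: int | None = None
                     ) -> AggregatedDeltaMap:
    """Aggregate window estimates onto non-overlapping W x W blocks.

    Blocks are aligned to the grid origin (trailing partial blocks are
    dropped); within each block every surviving window center contributes
    through the decorrelation weights, and ``support`` records the share of
    the block's cells that contributed.
    """
    B = block_size or delta.window_size
    n_months, n_trans, n_lat, n_lon = delta.delta.shape
    nb_lat, nb_lon = n_lat // B, n_lon // B
    if nb_lat == 0 or nb_lon == 0:
        raise ValueError("grid smaller than one aggregation block")
    out_delta = np.full((n_months, n_trans, nb_lat, nb_lon), np.nan)
    out_var = np.full_like(out_delta, np.nan)
    out_support = np.zeros_like(out_delta)
    rel = np.arange(B)
    rr, cc = np.meshgrid(rel, rel, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    full_overlap = window_overlap_matrix(rr, cc, delta.window_size)
    for bi in range(nb_lat):
        for bj in range(nb_lon):
            sl = (slice(None), slice(None),
                  slice(bi * B, (bi + 1) * B), slice(bj * B, (bj + 1) * B))
            d_blk = delta.delta[sl].reshape(n_months, n_trans, -1)
            s_blk = delta.sigma[sl].reshape(n_months, n_trans, -1)
            for mi in range(n_months):
                for ti in range(n_trans):
                    ok = np.isfinite(d_blk[mi, ti])
                    n_ok = int(ok.sum())
                    out_support[mi, ti, bi, bj] = n_ok / (B * B)
                    if n_ok == 0:
                        continue
                    mean, var, _ = decorrelated_aggregate(
                        d_blk[mi, ti][ok], s_blk[mi, ti][ok],
                        full_overlap[np.ix_(ok, ok)])
                    out_delta[mi, ti, bi, bj] = mean
                    out_var[mi, ti, bi, bj] = var
    blat = delta.lat[:nb_lat * B].reshape(nb_lat, B).mean(axis=1)
    blon = delta.lon[:nb_lon * B].reshape(nb_lon, B).mean(axis=1)
    return AggregatedDeltaMap(out_delta, out_var, out_support,
                              delta.transitions, blat, blon, B)


def filter_aggregates(agg: AggregatedDeltaMap, min_support: float = 0.2,
                      max_variance: float = 0.1,
                      percentiles: tuple[float, float] = (1.0, 99.0)
                      ) -> AggregatedDeltaMap:
    """Remove unreliable and outlying aggregated values.

    Drops blocks supported by less than ``min_support`` of the underlying
    centers or with methodological variance above ``max_variance``, then
    trims values outside the global [1st, 99th] percentiles computed per
    transition over all months pooled.
    """
    if not np.isfinite(agg.delta).any():
        raise ValueError("aggregate map is empty")
    out = agg.copy()
    bad = (out.support < min_support) | (out.variance > max_variance)
    out.delta[bad] = np.nan
    out.variance[bad] = np.nan
    for ti in range(len(agg.transitions)):
        vals = out.delta[:, ti]
        if not np.isfinite(vals).any():
            continue
        lo, hi = np.nanpercentile(vals, percentiles)
        trim = (vals < lo) | (vals > hi)
        vals[trim] = np.nan
        out.variance[:, ti][trim] = np.nan
    return replace(out, filters_applied=out.filters_applied
                   + ("support", "variance", "percentile"))


# --------------------------------------------------------------------------
# merging, normalisation, display, seasonal summary

def block_presence(fractions: FractionGrid, class_name: str,
                   block_size: int = 7) -> np.ndarray:
    """Block-mean fraction of one class (the merge weight per forest type)."""
    layer = fractions.layer(class_name)
    nb_lat = layer.shape[0] // block_size
    nb_lon = layer.shape[1] // block_size
    trimmed = layer[:nb_lat * block_size, :nb_lon * block_size]
    return trimmed.reshape(nb_lat, block_size, nb_lon, block_size).mean(axis=(1, 3))


def merge_forest_types(agg_decid: AggregatedDeltaMap, agg_evgr: AggregatedDeltaMap,
                       presence_decid: np.ndarray, presence_evgr: np.ndarray,
                       merged_label: tuple[str, str] = ("herbaceous", "forest")
                       ) -> AggregatedDeltaMap:
    """Presence-weighted merge of the deciduous and evergreen estimates.

    merged = (f_d * delta_d + f_e * delta_e) / (f_d + f_e) where both are
    present; blocks with a single estimated type pass that value through;
    blocks with neither stay missing. Variances are merged with the same
    weights.
    """
    if np.nanmin(presence_decid, initial=0) < 0 or np.nanmin(presence_evgr, initial=0) < 0:
        raise ValueError("presence fractions must be non-negative")
    if agg_decid.delta.shape != agg_evgr.delta.shape:
        raise ValueError("aggregated maps are not aligned")
    d, e = agg_decid.delta, agg_evgr.delta
    fd = np.broadcast_to(presence_decid, d.shape).copy()
    fe = np.broadcast_to(presence_evgr, e.shape).copy()
    fd = np.where(np.isfinite(d), fd, 0.0)
    fe = np.where(np.isfinite(e), fe, 0.0)
    total = fd + fe
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(total > 0,
                         (fd * np.nan_to_num(d) + fe * np.nan_to_num(e)) / total,
                         np.nan)
        var = np.where(total > 0,
                       (fd * np.nan_to_num(agg_decid.variance)
                        + fe * np.nan_to_num(agg_evgr.variance)) / total,
                       np.nan)
    support = np.fmax(agg_decid.support, agg_evgr.support)
    return AggregatedDeltaMap(delta, var, support, (merged_label,),
                              agg_decid.lat, agg_decid.lon, agg_decid.block_size,
                              agg_decid.filters_applied + ("forest_merge",))


def relative_change(agg: AggregatedDeltaMap, clouds: CloudGrid) -> np.ndarray:
    """Transition effect relative to the local monthly cloud climatology.

    Returns delta / (block-mean monthly CFrC), same shape as ``agg.delta``;
    blocks with zero or missing climatology become missing.
    """
    B = agg.block_size
    nb_lat, nb_lon = agg.delta.shape[2:]
    trimmed = clouds.clouds[:, :nb_lat * B, :nb_lon * B]
    block_cfrc = trimmed.reshape(12, nb_lat, B, nb_lon, B).mean(axis=(2, 4))
    n_months = agg.delta.shape[0]
    denom = block_cfrc[:n_months, None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = agg.delta / denom
    rel[~np.isfinite(rel)] = np.nan
    return rel


def coarsen_for_display(values: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                        factor: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted mean of non-missing blocks onto a coarser display grid.

    ``factor`` is the integer number of blocks per coarse cell along each
    axis (e.g. ~3 blocks of 0.35 degrees per 1-degree display cell).
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    *lead, n_lat, n_lon = values.shape
    nc_lat, nc_lon = n_lat // factor, n_lon // factor
    trimmed = values[..., :nc_lat * factor, :nc_lon * factor]
    shaped = trimmed.reshape(*lead, nc_lat, factor, nc_lon, factor)
    with np.errstate(invalid="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            coarse = np.nanmean(shaped, axis=(-3, -1))
    clat = lat[:nc_lat * factor].reshape(nc_lat, factor).mean(axis=1)
    clon = lon[:nc_lon * factor].reshape(nc_lon, factor).mean(axis=1)
    return coarse, clat, clon


def seasonal_positive_fraction(agg: AggregatedDeltaMap,
                               transition: tuple[str, str] | int = 0
                               ) -> pd.DataFrame:
    """Monthly share of blocks with a positive (and negative) effect.

    Southern-Hemisphere blocks are cycled by six months so that month 1
    means mid-winter everywhere; exact zeros are excluded from the
    denominator. Returns 12 rows (month, pct_positive, pct_negative,
    n_cells) plus the annual averages as a 13th row (month = 0).
    """
    ti = agg.transition_index(transition) if isinstance(transition, tuple) \
        else int(transition)
    n_months = agg.delta.shape[0]
    if n_months != 12:
        raise ValueError("seasonal summary needs 12 monthly layers")
    south = agg.lat < 0
    pos = np.zeros(12)
    neg = np.zeros(12)
    tot = np.zeros(12)
    for m in range(12):
        layer = agg.delta[m, ti]
        for hemi_mask, shift in ((~south, 0), (south, 6)):
            vals = layer[hemi_mask, :].ravel()
            vals = vals[np.isfinite(vals) & (vals != 0.0)]
            bin_m = (m + shift) % 12
            pos[bin_m] += (vals > 0).sum()
            neg[bin_m] += (vals < 0).sum()
            tot[bin_m] += vals.size
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_pos = np.where(tot > 0, 100.0 * pos / tot, np.nan)
        pct_neg = np.where(tot > 0, 100.0 * neg / tot, np.nan)
    rows = pd.DataFrame({"month": np.arange(1, 13), "pct_positive": pct_pos,
                         "pct_negative": pct_neg, "n_cells": tot.astype(int)})
    annual = pd.DataFrame({"month": [0],
                           "pct_positive": [np.nanmean(pct_pos)],
                           "pct_negative": [np.nanmean(pct_neg)],
                           "n_cells": [int(tot.sum())]})
    return pd.concat([rows, annual], ignore_index=True)
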