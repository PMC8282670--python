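"""Confront cloud-effect estimates with surface-energy-balance changes.

For every block where both a cloud-effect estimate and afforestation-driven
changes in the surface energy balance are available, records are placed in
a 2-D grid of energy-balance coordinates (e.g. net radiation change vs
latent-heat change) and the mean cloud change is reported per bin. Records
with a strong surface-albedo drop (Delta alpha below the snow threshold)
are snow-affected — dark trees replacing bright snow-covered open land —
and are binned as a separate stratum. Bins with few records are flagged
non-representative rather than dropped, so the display can grey them out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bin_energy_balance"]

#: Albedo-change threshold separating snow-affected records. The companion
#: value -0.1 is sometimes used for the same split; pass it explicitly to
#: reproduce that variant.
SNOW_ALBEDO_THRESHOLD = -0.15


def bin_energy_balance(records: pd.DataFrame, x_var: str, y_var: str,
                       x_edges: np.ndarray, y_edges: np.ndarray,
                       value_var: str = "d_cfrc",
                       snow_var: str = "d_alpha",
                       snow_threshold: float = SNOW_ALBEDO_THRESHOLD,
                       min_records: int = 15) -> pd.DataFrame:
    """Mean cloud change on a 2-D grid of energy-balance changes.

    Records are split into a ``no_snow`` stratum (snow_var >= threshold) and
    a ``snow`` stratum, then assigned to half-open bins [lo, hi) on both
    axes; records outside the edges are dropped (their count is kept in
    ``result.attrs['n_dropped']``). Each output row is one populated bin:
    stratum, bin indices and edges, mean value, count, and a
    ``representative`` flag (count >= min_records).
    """
    if records.empty:
        raise ValueError("empty record set")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    x = records[x_var].to_numpy(dtype=float)
    y = records[y_var].to_numpy(dtype=float)
    v = records[value_var].to_numpy(dtype=float)
    snow = records[snow_var].to_numpy(dtype=float) < snow_threshold

    ix = np.digitize(x, x_edges) - 1
    iy = np.digitize(y, y_edges) - 1
    in_range = ((ix >= 0) & (ix < x_edges.size - 1)
                & (iy >= 0) & (iy < y_edges.size - 1)
                & np.isfinite(v))
    n_dropped = int((~in_range).sum())

    frame = pd.DataFrame({
        "stratum": np.where(snow[in_range], "snow", "no_snow"),
        "x_bin": ix[in_range], "y_bin": iy[in_range], "value": v[in_range],
    })
    grouped = (frame.groupby(["stratum", "x_bin", "y_bin"])["value"]
               .agg(["mean", "count"]).reset_index()
               .rename(columns={"mean": "mean_value"}))
    grouped["x_lo"] = x_edges[grouped["x_bin"]]
    grouped["x_hi"] = x_edges[grouped["x_bin"] + 1]
    grouped["y_lo"] = y_edges[grouped["y_bin"]]
    grouped["y_hi"] = y_edges[grouped["y_bin"] + 1]
    grouped["representative"] = grouped["count"] >= min_records
    grouped.attrs["n_dropped"] = n_dropped
    return grouped
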