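"""Aggregate the masked effect maps and build the headline summaries.

Takes the masked per-cell maps from 02, aggregates them to 0.35-degree
blocks with decorrelation weights, applies the support/variance/percentile
filters, merges the two forest types by presence, expresses the effect
relative to local cloudiness, coarsens for display, and writes the
monthly positive-fraction table.

Run from the repository root:  python analysis/03_aggregate_and_summarize.py
"""

from pathlib import Path

import numpy as np

from cloudshift.grids import CloudGrid, DeltaMap, FractionGrid
from cloudshift.postprocess import (aggregate_blocks, block_presence,
                                    coarsen_for_display, filter_aggregates,
                                    merge_forest_types, relative_change,
                                    seasonal_positive_fraction)

WORLD = Path("results/world")
OUT = Path("results")


def single_transition(agg, ti):
    from dataclasses import replace
    return replace(agg, delta=agg.delta[:, ti:ti + 1],
                   variance=agg.variance[:, ti:ti + 1],
                   support=agg.support[:, ti:ti + 1],
                   transitions=(agg.transitions[ti],))


def main() -> None:
    dm = DeltaMap.open(OUT / "delta_masked.nc")
    fractions = FractionGrid.open(WORLD / "fractions.nc")
    clouds = CloudGrid.open(WORLD / "clouds.nc")

    agg = filter_aggregates(aggregate_blocks(dm))
    grand = np.nanmean(agg.delta)
    print(f"aggregated blocks: {int(np.isfinite(agg.delta).sum())}, "
          f"grand-mean effect {grand:+.4f} (planted +0.0500)")

    merged = merge_forest_types(
        single_transition(agg, 0), single_transition(agg, 1),
        block_presence(fractions, "deciduous_forest")[None, None],
        block_presence(fractions, "evergreen_forest")[None, None])
    merged.to_netcdf(OUT / "aggregated_merged.nc")

    rel = relative_change(merged, clouds)
    print(f"median relative effect {100 * np.nanmedian(rel):+.1f}% "
          f"of local monthly cloudiness")

    coarse, clat, clon = coarsen_for_display(merged.delta, merged.lat,
                                             merged.lon, 3)
    print(f"display grid: {coarse.shape[-2]}x{coarse.shape[-1]} cells "
          f"of ~1 degree")

    table = seasonal_positive_fraction(merged)
    table.to_csv(OUT / "seasonal_positive_fraction.csv", index=False)
    annual = table[table.month == 0].iloc[0]
    print(f"blocks with increased cloudiness: {annual.pct_positive:.1f}% "
          f"(annual mean over months)")


if __name__ == "__main__":
    main()
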