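"""Validate the satellite effect against paired ground stations.

Reads the simulated station network from results/world/, attaches the
15 km land-cover context, filters for water/orography/record length,
pairs stations 30-100 km apart, and fits the forced-origin regression of
cloud-cover difference on forest-fraction difference per month and hour.
The 14:00 slopes are compared with the aggregated satellite estimates
within 50 km of each pair.

Run from the repository root:  python analysis/05_station_validation.py
(requires 01 and 03)
"""

from pathlib import Path


from cloudshift.grids import AggregatedDeltaMap
from cloudshift.station_validation import (StationTable, compare_with_satellite,
                                           filter_stations, pair_stations,
                                           pairwise_deltas, slope_matrix)

WORLD = Path("results/world")
OUT = Path("results")


def load_merged():
    import xarray as xr
    ds = xr.open_dataset(OUT / "aggregated_merged.nc", engine="scipy")
    transitions = tuple(tuple(lbl.split("->"))
                        for lbl in ds.attrs["transitions"].split(";"))
    return AggregatedDeltaMap(ds["delta"].values, ds["variance"].values,
                              ds["support"].values, transitions,
                              ds["lat"].values, ds["lon"].values,
                              int(ds.attrs["block_size"]))


def main() -> None:
    table = StationTable.read_csv(WORLD / "stations.csv",
                                  WORLD / "station_records.csv")
    # context (forest/water/orography) is attached as truth by the simulator
    filtered = filter_stations(table)
    print(f"stations: {len(table.stations)} -> {len(filtered.stations)} "
          f"after water/orography/record filters")

    pairs = pair_stations(filtered.stations)
    deltas = pairwise_deltas(pairs, filtered)
    print(f"pairs 30-100 km apart: {len(pairs)}")

    sm = slope_matrix(deltas)
    sm.to_csv(OUT / "station_slopes.csv", index=False)
    at14 = sm[sm.hour == 14]
    print(f"forced-origin slope at 14:00, mean over months: "
          f"{at14.slope.mean():+.4f} +/- {at14.se.mean():.4f} "
          f"(planted +0.0500); significant in "
          f"{int(at14.significant.sum())}/12 months")

    merged = load_merged()
    comparison = compare_with_satellite(pairs, deltas, merged)
    comparison.to_csv(OUT / "station_vs_satellite.csv", index=False)
    diff = comparison["ground_slope"] - comparison["satellite_mean"]
    print(f"ground minus satellite, mean over months: {diff.mean():+.4f} "
          f"cloud fraction")
    print(f"tables written to {OUT / 'station_slopes.csv'} and "
          f"{OUT / 'station_vs_satellite.csv'}")


if __name__ == "__main__":
    main()
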