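"""Generate the synthetic study region and write every pipeline input.

Creates a 120x120-cell world at 0.05 degrees (a herbaceous/forest mosaic
with minor classes), its noiseless and noisy cloud climatologies, flat and
ridge elevation scenarios, and a seven-year ground-station network, under
results/world/.

Run from the repository root:  python analysis/01_simulate_world.py
"""

from pathlib import Path

import numpy as np

from cloudshift.ingest import elevation_window_stats
from cloudshift.synthetic_world import (WorldConfig, default_response,
                                        generate_cloud_truth,
                                        generate_elevation, generate_landcover,
                                        generate_station_records)

SEED = 42
OUT = Path("results/world")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = WorldConfig(n_lat=120, n_lon=120, seed=SEED)
    fractions = generate_landcover(cfg)
    fractions.validate_closure()
    fractions.to_netcdf(OUT / "fractions.nc")

    response = default_response(noise_sd=0.01)
    clouds = generate_cloud_truth(fractions, response, seed=SEED)
    clouds.to_netcdf(OUT / "clouds.nc")

    for scenario in ("flat", "ridge"):
        elev = generate_elevation(cfg, scenario)
        elev.to_netcdf(OUT / f"elevation_{scenario}.nc")
        elevation_window_stats(elev).to_netcdf(OUT / f"topo_{scenario}.nc")

    stations = generate_station_records(cfg, n_stations=60, years=7,
                                        slope=0.05, seed=SEED)
    stations.write_csv(OUT / "stations.csv", OUT / "station_records.csv")

    herb = fractions.layer("herbaceous").mean()
    forest = (fractions.layer("deciduous_forest")
              + fractions.layer("evergreen_forest")).mean()
    print(f"world: {cfg.n_lat}x{cfg.n_lon} cells, seed {SEED}")
    print(f"mean cover  herbaceous {herb:.2f}  forest {forest:.2f}")
    print(f"cloud range {clouds.clouds.min():.3f}-{clouds.clouds.max():.3f} "
          f"(planted forest effect +0.05, noise sd 0.01)")
    print(f"stations: {len(stations.stations)}, "
          f"records: {len(stations.records)}")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
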