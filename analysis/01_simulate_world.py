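"""Generate the synthetic study world and write its input files.

Produces a self-contained input bundle under scratch/world/ — sparse anchor
deposition maps (the decadal + 1997-2013 availability pattern), annual
emission maps 1970-2018, cropland sub-type fractions on a 4x finer grid, a
country-code mask, station records and a nutrient-budget table — plus the
generator's ground-truth national table for later comparison.
"""

import sys
from pathlib import Path

import numpy as np

from cropdep import WorldConfig, degrade_to_anchors, generate_world
from cropdep.io import (write_gridded, write_mask_netcdf, write_national_table)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "world"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    world = generate_world(WorldConfig(nlat=20, nlon=40, refine=4,
                                       n_countries=8, sigma=0.0, seed=SEED))
    anchors = degrade_to_anchors(world.deposition_truth)
    for y, fld in anchors.items():
        write_gridded(fld, OUT / f"dep_anchor_{y}.nc", "deposition")
    for y, fld in world.emissions.items():
        write_gridded(fld, OUT / f"emission_{y}.nc", "emission")
    for t, fld in world.cropland_fractions[0].items():
        write_gridded(fld, OUT / f"cropland_frac_{t}.nc", "fraction")
    write_mask_netcdf(world.mask, OUT / "mask.nc")
    world.stations.to_csv(OUT / "stations.csv", index=False)
    world.budget.to_csv(OUT / "budget.csv", index=False)
    write_national_table(world.truth_rates, OUT / "truth_rates")

    n_withheld = 60 - sum(1 for y in anchors if 1961 <= y <= 2020)
    print(f"world seed={SEED}: {world.grid.nlat}x{world.grid.nlon} deposition grid, "
          f"{world.fine_grid.nlat}x{world.fine_grid.nlon} cropland grid, "
          f"{world.mask.n_countries} countries")
    print(f"anchor maps retained: {len(anchors)} (incl. 1960); "
          f"{n_withheld} of 60 product years must be gap-filled")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
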