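# cropdep

National-scale annual nitrogen-deposition inputs to cropland, 1961–2020.

Atmospheric deposition of reactive nitrogen is a significant nutrient input
to cropland and a required term in national nitrogen budgets and
nitrogen-use-efficiency (NUE) assessments. Gridded deposition fields from
chemistry-transport models exist only for scattered years, at coarser
resolution than cropland maps, and without country attribution. `cropdep`
turns such inputs into country × year tables of cropland N deposition:

* **Grid geometry** — spherical cell areas, conservative fine-to-coarse
  regridding of extensive fields, fractional country masks from polygons or
  code grids.
* **Cropland adapters** — decadal-map year rules (HYDE-style) and the
  max-of-five-crop-type-fractions rule (LUH2-style), with hold rules past
  the last available map.
* **Gap-filling** — per-cell linear interpolation in year between the 1960
  and 1970 maps (`dep = β₀ + β₁·Y`), per-cell OLS of deposition on N
  emission over anchor years (`dep = β₀ + β₁·N_emission`) for 1971–1996 and
  2014–2018, and a 2018 hold for 2019–2020.
* **National aggregation** — cropland-area-weighted mean rates
  (kg N ha⁻¹ yr⁻¹) and totals (Tg N yr⁻¹) per country, NaN for countries
  without cropland.
* **Station validation** — precipitation-chemistry arithmetic
  (`kg N ha⁻¹ day⁻¹ = mg L⁻¹ × mm × 0.01`, annualized as `365 × mean`) and
  product-vs-station distribution summaries.
* **NUE sensitivity** — `NUE = N_CR / (N_SF + N_MN + N_BNF + N_AD)` and the
  difference / per-country correlation of NUE across deposition products.
* **Synthetic world** — a seeded generator with exactly recoverable ground
  truth, used by the test suite and the analysis scripts.

## Worked example

```python
import numpy as np
from cropdep import (WorldConfig, generate_world, degrade_to_anchors,
                     complete_series, build_national_table)

world = generate_world(WorldConfig(nlat=20, nlon=40, refine=4,
                                   n_countries=8, sigma=0.0, seed=1))
anchors = degrade_to_anchors(world.deposition_truth)   # 21 anchor maps
series = complete_series(anchors, world.emissions)     # fill 1961-2020
rates = build_national_table(series, world.cropland_series,
                             world.mask, kind="rate")
print(rates.loc["C005", 2000])                         # 13.76 kg N ha-1 yr-1
err = (rates - world.truth_rates).abs()
print(float(np.nanmax(err.to_numpy())))                # 1.6e-14
```

The generator withholds 40 of the 60 product years; the gap-filling
regressions reconstruct them exactly (the synthetic world is affine in
emission and linear in year by construction), so the recovered national
table matches the independently computed ground truth to rounding error.

The same chain is available as an analysis narrative and from the shell:

```bash
python analysis/01_simulate_world.py      # write synthetic inputs
python analysis/02_build_products.py      # gap-fill + aggregate -> results/products/
python analysis/03_validate_stations.py   # station comparison  -> results/
python analysis/04_nue_sensitivity.py     # NUE difference/correlation -> results/nue/
# or: cropdep synth --seed 1 --out world/ && cropdep build --in world/ --out products/
```

`02_build_products.py` prints, for the seed-1 world:

```
max |recovered - truth| national rate: 1.599e-14 kg N ha-1 yr-1
global cropland N deposition in 2000: 151.25 Tg N yr-1
```

and `03_validate_stations.py` reports the 2000 product value inside the
station interquartile range for all 8 synthetic countries.

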