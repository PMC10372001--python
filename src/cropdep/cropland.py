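"""Cropland-map adapters: turn HYDE-style and LUH2-style inputs into annual
cropland-area fields (ha) on the deposition grid for 1961-2020.

Two source conventions are supported.  HYDE-style inputs are decadal maps up
to 2000 and annual maps 2001-2017, either as area (ha) or as a cropland
fraction of the cell.  LUH2-style inputs are annual per-crop-type fraction
fields (C3 annual, C3 perennial, C4 annual, C4 perennial, C3 N-fixing) up to
2015; the cropland fraction of a cell is the maximum over the five sub-types.
Years past the last available map hold the last map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AnnualField, GridSpec, cell_areas, regrid_sum

YEARS = range(1961, 2021)

LUH2_CROP_TYPES = ("c3ann", "c3per", "c4ann", "c4per", "c3nfx")


def hyde_year_map(year: int) -> int:
    """Source cropland-map year used for a given series year (HYDE rules).

    Decadal maps serve 1961-2000 (each decade's map covers the surrounding
    years, with 1996-2000 served by the 2000 map), annual maps serve
    2001-2017, and 2018-2020 hold the 2017 map.
    """
    if not 1961 <= year <= 2020:
        raise ValueError(f"year {year} outside supported range 1961-2020")
    if year <= 1965:
        return 1960
    if year <= 1975:
        return 1970
    if year <= 1985:
        return 1980
    if year <= 1995:
        return 1990
    if year <= 2000:
        return 2000
    if year <= 2017:
        return year
    return 2017


def luh2_year_hold(year: int, last_available: int = 2015) -> int:
    """Identity up to ``last_available``; later years hold the last map."""
    if not 1961 <= year <= 2020:
        raise ValueError(f"year {year} outside supported range 1961-2020")
    return min(year, last_available)


def luh2_cropland_area(fractions: dict[str, AnnualField],
                       deposition_grid: GridSpec,
                       combine: str = "max") -> AnnualField:
    """Cropland area (ha) on the deposition grid from per-type fractions.

    The per-cell cropland fraction is the maximum (default) or the sum of
    the five sub-type fractions; fraction x spherical cell area gives area
    at native resolution, which is then conservatively summed to the
    deposition grid.
    """
    missing = [t for t in LUH2_CROP_TYPES if t not in fractions]
    if missing:
        raise ValueError(f"missing cropland sub-type fractions: {missing}")
    fields = [fractions[t] for t in LUH2_CROP_TYPES]
    g = fields[0].grid
    for f in fields[1:]:
        if f.grid != g:
            raise ValueError("sub-type fraction fields are not co-registered")
    stack = np.stack([f.values for f in fields])
    if np.nanmin(stack) < -1e-12 or np.nanmax(stack) > 1 + 1e-12:
        raise ValueError("cropland fractions must lie in [0, 1]")
    if combine == "max":
        frac = stack.max(axis=0)
    elif combine == "sum":
        frac = np.clip(stack.sum(axis=0), 0.0, 1.0)
    else:
        raise ValueError("combine must be 'max' or 'sum'")
    area = frac * cell_areas(g).values
    native = AnnualField(g, area, units="ha", year=fields[0].year)
    if g == deposition_grid:
        return native
    return regrid_sum(native, deposition_grid)


def hyde_cropland_area(source: AnnualField, deposition_grid: GridSpec) -> AnnualField:
    """HYDE-style map (area in ha, or fraction) -> area on the deposition grid."""
    if source.units == "1":
        native = AnnualField(source.grid, source.values * cell_areas(source.grid).values,
                             units="ha", year=source.year)
    elif source.units == "ha":
        native = source
    else:
        raise ValueError(f"cropland input must be 'ha' or fraction '1', got {source.units!r}")
    if source.grid == deposition_grid:
        return native
    return regrid_sum(native, deposition_grid)


@dataclass
class CroplandSeries:
    """Annual cropland area fields (ha) on the deposition grid, 1961-2020."""

    fields: dict[int, AnnualField]
    provenance: str  # "hyde-like" | "luh2-like"
    source_years: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        missing = [y for y in YEARS if y not in self.fields]
        if missing:
            raise ValueError(f"cropland series missing years {missing[:5]}...")

    def __getitem__(self, year: int) -> AnnualField:
        return self.fields[year]


def build_cropland_series(source_maps, deposition_grid: GridSpec, *,
                          source: str, luh2_combine: str = "max",
                          luh2_last_year: int = 2015) -> CroplandSeries:
    """Assemble the 1961-2020 cropland-area series.

    ``source_maps`` maps source year -> AnnualField (hyde) or source year ->
    {type: fraction AnnualField} (luh2).  Year mapping follows the source's
    availability rules; each mapped source map is converted once and reused.
    """
    if source not in ("hyde", "luh2"):
        raise ValueError("source must be 'hyde' or 'luh2'")
    cache: dict[int, AnnualField] = {}
    out, src_years = {}, {}
    for year in YEARS:
        sy = hyde_year_map(year) if source == "hyde" else luh2_year_hold(year, luh2_last_year)
        if sy not in source_maps:
            raise ValueError(f"required source cropland map for year {sy} is missing")
        if sy not in cache:
            if source == "hyde":
                cache[sy] = hyde_cropland_area(source_maps[sy], deposition_grid)
            else:
                cache[sy] = luh2_cropland_area(source_maps[sy], deposition_grid,
                                               combine=luh2_combine)
        f = cache[sy]
        out[year] = AnnualField(f.grid, f.values, units="ha", year=year)
        src_years[year] = sy
    return CroplandSeries(out, provenance=f"{source}-like", source_years=src_years)
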