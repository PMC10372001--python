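"""Readers and writers for the pipeline's on-disk formats.

Gridded fields travel as CF-style NetCDF (classic format via the SciPy
backend) with 1-D ``lat``/``lon`` coordinate variables; national tables are
written as CSV (primary) and XLSX mirroring the published layout — one row
per country, one column per year, literal ``NaN`` for undefined cells.
Country masks may arrive as NetCDF integer code grids or GeoJSON polygon
collections.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import AnnualField, CountryMask, GridSpec, mask_from_codes, rasterize_countries

_LAT_NAMES = ("lat", "latitude")
_LON_NAMES = ("lon", "longitude")

#: File stems for the four deposition products, in conventional order.
PRODUCT_FILE_STEMS = {"AH": "1_AH", "AL": "2_AL", "WH": "3_WH", "WL": "4_WL"}


def _find_coord(ds: xr.Dataset, names) -> str:
    for n in names:
        if n in ds.coords or n in ds.variables:
            return n
    raise ValueError(f"no coordinate named one of {names} in dataset "
                     f"(found {sorted(ds.variables)})")


def read_gridded(path, variable: str, units: str,
                 year: int | None = None) -> AnnualField:
    """Read one 2-D (lat, lon) variable into an AnnualField.

    Latitude orientation is normalized (ascending); a ``year`` stored as an
    attribute or passed explicitly is attached to the field.
    """
    with xr.open_dataset(path) as ds:
        if variable not in ds:
            raise ValueError(
                f"variable {variable!r} not in {path}; available: {sorted(ds.data_vars)}")
        da = ds[variable].load()
        lat_name = _find_coord(ds, _LAT_NAMES)
        lon_name = _find_coord(ds, _LON_NAMES)
        lat = np.asarray(ds[lat_name].values, dtype=float)
        lon = np.asarray(ds[lon_name].values, dtype=float)
        vals = np.asarray(da.transpose(lat_name, lon_name).values, dtype=float)
        if lat.size > 1 and lat[1] < lat[0]:
            lat, vals = lat[::-1], vals[::-1, :]
        if year is None and "year" in da.attrs:
            year = int(da.attrs["year"])
    grid = GridSpec(lat, lon)
    return AnnualField(grid, vals, units=units, year=year)


def write_gridded(field: AnnualField, path, variable: str = "value") -> None:
    """Write an AnnualField as classic NetCDF with CF-style coordinates."""
    da = xr.DataArray(
        field.values,
        coords={"lat": field.grid.lat_centers, "lon": field.grid.lon_centers},
        dims=("lat", "lon"), name=variable,
        attrs={"units": field.units, **({"year": field.year} if field.year is not None else {})},
    )
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_mask_netcdf(path, variable: str = "country_id",
                     codes=None) -> CountryMask:
    """CountryMask from a pre-rasterized integer country-code grid.

    Country labels come from ``codes`` or from a space-separated
    ``countries`` attribute written by :func:`write_mask_netcdf`.
    """
    with xr.open_dataset(path) as ds:
        if variable not in ds:
            raise ValueError(
                f"variable {variable!r} not in {path}; available: {sorted(ds.data_vars)}")
        da = ds[variable].load()
        lat_name = _find_coord(ds, _LAT_NAMES)
        lon_name = _find_coord(ds, _LON_NAMES)
        lat = np.asarray(ds[lat_name].values, dtype=float)
        lon = np.asarray(ds[lon_name].values, dtype=float)
        vals = np.asarray(da.transpose(lat_name, lon_name).values)
        if lat.size > 1 and lat[1] < lat[0]:
            lat, vals = lat[::-1], vals[::-1, :]
        if codes is None and "countries" in da.attrs:
            attr = da.attrs["countries"]
            if isinstance(attr, bytes):
                attr = attr.decode()
            codes = attr.split()
    return mask_from_codes(vals.astype(int), GridSpec(lat, lon), codes)


def write_mask_netcdf(mask: CountryMask, path, variable: str = "country_id") -> None:
    """Persist a 0/1 mask as an integer code grid (-1 = no country).

    Fractional masks cannot round-trip through a code grid; they raise.
    """
    hard = mask.shares
    if not np.all((hard < 1e-12) | (np.abs(hard - 1) < 1e-12)):
        raise ValueError("fractional mask cannot be written as a code grid")
    codes = np.full(mask.grid.shape, -1.0)
    for k in range(mask.n_countries):
        codes[hard[k] > 0.5] = k
    da = xr.DataArray(codes, coords={"lat": mask.grid.lat_centers,
                                     "lon": mask.grid.lon_centers},
                      dims=("lat", "lon"), name=variable,
                      attrs={"countries": " ".join(mask.countries)})
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_mask_geojson(path, grid: GridSpec, code_property: str = "iso3") -> CountryMask:
    """Rasterize a GeoJSON FeatureCollection of country polygons."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    polys = {feat["properties"][code_property]: shape(feat["geometry"])
             for feat in gj["features"]}
    return rasterize_countries(polys, grid)


def write_national_table(table: pd.DataFrame, path_stem) -> tuple[Path, Path]:
    """Write a country x year table as CSV and XLSX.

    Rows are sorted by ISO3 code; the first column is the country code; NaN
    cells are written as the literal ``NaN``.  Returns the two paths.
    """
    path_stem = Path(path_stem)
    path_stem.parent.mkdir(parents=True, exist_ok=True)
    out = table.sort_index()
    csv_path = path_stem.with_suffix(".csv")
    xlsx_path = path_stem.with_suffix(".xlsx")
    out.to_csv(csv_path, na_rep="NaN")
    out.to_excel(xlsx_path, na_rep="NaN")
    return csv_path, xlsx_path


def read_national_table(path) -> pd.DataFrame:
    """Round-trip reader for the CSV national table."""
    df = pd.read_csv(path, index_col=0, na_values=["NaN"])
    df.columns = [int(c) for c in df.columns]
    df.index.name = "country"
    return df


def read_budget_csv(path) -> pd.DataFrame:
    """Long budget table: country, year, n_cr, n_sf, n_mn, n_bnf, n_ad_*."""
    df = pd.read_csv(path)
    req = {"country", "year", "n_cr", "n_sf", "n_mn", "n_bnf"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"budget CSV missing columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    """Flat key-value run configuration (YAML)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping")
    return cfg
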