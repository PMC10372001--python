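"""Cropland-area-weighted national aggregation of gridded deposition rates.

The national deposition rate of country ``c`` for one year is the weighted
mean of cell deposition rates, with weights ``w_i = cropland_i * share_ic``
(cropland area in the cell times the fraction of the cell inside the
country).  Countries with zero cropland weight get NaN.  National totals are
``rate * cropland area * 1e-9`` (kg -> Tg).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import AnnualField, CountryMask


def country_cropland_area(cropland: AnnualField, mask: CountryMask) -> pd.Series:
    """Cropland area (ha) per country: sum of cell cropland times shares."""
    if cropland.grid != mask.grid:
        raise ValueError("cropland and mask are on different grids")
    crop = np.nan_to_num(cropland.values, nan=0.0)
    areas = (mask.shares * crop[None, :, :]).sum(axis=(1, 2))
    return pd.Series(areas, index=pd.Index(mask.countries, name="country"), name="cropland_ha")


def national_rate(dep: AnnualField, cropland: AnnualField, mask: CountryMask) -> pd.Series:
    """Cropland-weighted mean deposition rate per country (kg N ha-1 yr-1)."""
    if dep.grid != cropland.grid or dep.grid != mask.grid:
        raise ValueError("deposition, cropland and mask must share one grid")
    crop = np.nan_to_num(cropland.values, nan=0.0)
    d = dep.values
    ok = np.isfinite(d)
    w = mask.shares * (crop * ok)[None, :, :]
    num = (w * np.where(ok, d, 0.0)[None, :, :]).sum(axis=(1, 2))
    den = w.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(den > 0, num / den, np.nan)
    return pd.Series(rates, index=pd.Index(mask.countries, name="country"),
                     name=dep.year)


def national_total(rate_row: pd.Series, cropland_by_country: pd.Series,
                   nan_zero_area: str = "zero") -> pd.Series:
    """National deposition totals (Tg N yr-1) from rates and cropland areas.

    ``nan_zero_area`` controls countries with zero cropland: ``"zero"`` gives
    a 0 total, ``"nan"`` propagates NaN.
    """
    area = cropland_by_country.reindex(rate_row.index)
    if (area.dropna() < 0).any():
        raise ValueError("negative cropland area")
    total = rate_row * area * 1e-9
    zero = area.fillna(0.0) == 0
    total[zero] = 0.0 if nan_zero_area == "zero" else np.nan
    return total.rename(rate_row.name)


def build_national_table(dep_series, cropland_series, mask: CountryMask,
                         kind: str = "rate") -> pd.DataFrame:
    """Country x year table of rates (kg N ha-1 yr-1) or totals (Tg N yr-1).

    ``dep_series`` and ``cropland_series`` are mappings year -> AnnualField
    (a DepositionSeries / CroplandSeries both qualify).
    """
    dep_years = set(dep_series.years if hasattr(dep_series, "years")
                    else dep_series.keys())
    crop_years = set(cropland_series.fields.keys()
                     if hasattr(cropland_series, "fields") else cropland_series.keys())
    years = sorted(dep_years & crop_years)
    cols = {}
    for y in years:
        dep = dep_series[y]
        crop = cropland_series[y]
        rate = national_rate(dep, crop, mask)
        if kind == "rate":
            cols[y] = rate
        elif kind == "total":
            cols[y] = national_total(rate, country_cropland_area(crop, mask))
        else:
            raise ValueError("kind must be 'rate' or 'total'")
    table = pd.DataFrame(cols)
    table.index.name = "country"
    return table.sort_index()
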