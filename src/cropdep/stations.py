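"""Station precipitation-chemistry records and product-vs-station comparison.

Daily records give total-N concentration (mg/L) and precipitation (mm); the
daily wet-deposition flux is ``conc * precip * 0.01`` kg N/ha/day (1 mm of
rain on 1 ha is 1e4 L, so 1 mg/L over 1 mm deposits 10 g/ha = 0.01 kg/ha).
Annual flux is ``365 * mean(daily fluxes over days with data)``; 365 is used
for every year, leap years included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.0
MM_MGL_TO_KG_HA = 0.01


def daily_flux(conc_mg_per_l, precip_mm):
    """Wet N flux (kg N ha-1 day-1) from concentration (mg/L) and rain (mm)."""
    conc = np.asarray(conc_mg_per_l, dtype=float)
    precip = np.asarray(precip_mm, dtype=float)
    if np.nanmin(conc, initial=0.0) < 0 or np.nanmin(precip, initial=0.0) < 0:
        raise ValueError("concentration and precipitation must be non-negative")
    out = conc * precip * MM_MGL_TO_KG_HA
    return float(out) if out.ndim == 0 else out


def annualize(daily_fluxes) -> float:
    """Annual flux (kg N ha-1 yr-1): 365 x mean of available daily fluxes.

    Returns NaN when no days are available.
    """
    f = np.asarray(daily_fluxes, dtype=float)
    f = f[np.isfinite(f)]
    if f.size == 0:
        return float("nan")
    return float(DAYS_PER_YEAR * f.mean())


@dataclass
class StationSeries:
    """Daily records for one station plus their annualized fluxes."""

    station_id: str
    lat: float
    lon: float
    daily: pd.DataFrame  # columns: date, total_n_mg_per_l, precip_mm

    def __post_init__(self):
        req = {"date", "total_n_mg_per_l", "precip_mm"}
        if not req <= set(self.daily.columns):
            raise ValueError(f"daily records need columns {sorted(req)}")
        d = self.daily
        if (d["total_n_mg_per_l"].dropna() < 0).any() or (d["precip_mm"].dropna() < 0).any():
            raise ValueError("negative concentration or precipitation")

    def annual_flux(self) -> pd.Series:
        """kg N ha-1 yr-1 per calendar year, NaN-free (years w/o data omitted)."""
        d = self.daily.copy()
        d["year"] = pd.to_datetime(d["date"]).dt.year
        d["flux"] = daily_flux(d["total_n_mg_per_l"].to_numpy(),
                               d["precip_mm"].to_numpy())
        out = d.dropna(subset=["flux"]).groupby("year")["flux"].mean() * DAYS_PER_YEAR
        out.name = self.station_id
        return out


def read_station_csv(path) -> list[StationSeries]:
    """Read the generic station CSV (station_id, date, lat, lon,
    total_n_mg_per_l, precip_mm) into StationSeries objects."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for sid, g in df.groupby("station_id"):
        lat = float(g["lat"].iloc[0]) if "lat" in g else float("nan")
        lon = float(g["lon"].iloc[0]) if "lon" in g else float("nan")
        out.append(StationSeries(str(sid), lat, lon,
                                 g[["date", "total_n_mg_per_l", "precip_mm"]].reset_index(drop=True)))
    return out


def percentile(sorted_values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile between order statistics (the
    convention numpy calls 'linear'); kept explicit so the definition used in
    comparisons is documented and testable."""
    v = np.sort(np.asarray(sorted_values, dtype=float))
    if v.size == 0:
        return float("nan")
    h = (v.size - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def compare_to_stations(product: pd.DataFrame, stations: list[StationSeries],
                        years=None, country: str | None = None) -> pd.DataFrame:
    """Summarize product national values against station annual-flux spreads.

    For each year with at least one station annual value: the station
    median and 25th/75th percentiles, the product value, and flags for the
    product falling inside the interquartile range and inside the full
    station range.  ``product`` is a country x year table; ``country``
    selects the row (defaults to the single row present).
    """
    if country is None:
        if len(product.index) != 1:
            raise ValueError("specify country for a multi-country product table")
        country = product.index[0]
    annuals = [s.annual_flux() for s in stations]
    all_years = sorted(set().union(*[set(a.index) for a in annuals])) if annuals else []
    if years is not None:
        all_years = [y for y in all_years if y in set(years)]
    rows = []
    for y in all_years:
        vals = np.array([a.loc[y] for a in annuals if y in a.index], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0 or y not in product.columns:
            continue
        p = float(product.loc[country, y])
        q25, q50, q75 = (percentile(vals, q) for q in (25, 50, 75))
        rows.append({
            "year": y, "n_stations": vals.size,
            "station_p25": q25, "station_median": q50, "station_p75": q75,
            "station_min": float(vals.min()), "station_max": float(vals.max()),
            "product": p,
            "within_iqr": bool(q25 <= p <= q75),
            "within_range": bool(vals.min() <= p <= vals.max()),
        })
    return pd.DataFrame(rows).set_index("year") if rows else pd.DataFrame(
        columns=["n_stations", "station_p25", "station_median", "station_p75",
                 "station_min", "station_max", "product", "within_iqr", "within_range"])
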