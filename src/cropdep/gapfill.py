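"""Temporal gap-filling of gridded N-deposition series from anchor years.

Deposition maps are often available only for scattered anchor years (for the
LMDZ-OR-INCA-style product: 1960, 1970, 1980, 1990 and 1997-2013) while
emission inventories are annual (1970-2018).  The missing years are filled
per grid cell:

* 1961-1969 — straight line in calendar year through the 1960 and 1970 maps
  (``dep = b0 + b1*year``);
* 1971-1996 non-anchor years — ordinary least squares of deposition on total
  N emission over the early anchors {1970, 1980, 1990, 1997}, evaluated at
  each year's emission (``dep = b0 + b1*emission``);
* 2014-2018 — the same emission regression refit on the late anchors
  1997-2013;
* 2019-2020 — emission data end in 2018, so the 2018 map is held.

All regressions are fit independently per cell; negative predictions are
clipped at zero (deposition is a non-negative flux).  Cells with no emission
variance fall back to the mean anchor-year deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AnnualField, GridSpec

EARLY_ANCHORS = (1970, 1980, 1990, 1997)
LATE_ANCHORS = tuple(range(1997, 2014))
WANG_ANCHOR_PATTERN = (1960, 1970, 1980, 1990) + LATE_ANCHORS


def assemble_total(dry_nhy: AnnualField, wet_nhy: AnnualField,
                   dry_nox: AnnualField, wet_nox: AnnualField) -> AnnualField:
    """Bulk N deposition: cellwise sum of the four dry/wet x NHy/NOx parts."""
    parts = (dry_nhy, wet_nhy, dry_nox, wet_nox)
    g, u, y = parts[0].grid, parts[0].units, parts[0].year
    for p in parts[1:]:
        if p.grid != g:
            raise ValueError("component fields are on different grids")
        if p.units != u or p.year != y:
            raise ValueError("component fields disagree in units or year")
    return AnnualField(g, sum(p.values for p in parts), units=u, year=y)


@dataclass
class RegressionParams:
    """Per-cell intercept/slope of a linear gap-filling relation."""

    grid: GridSpec
    beta0: np.ndarray
    beta1: np.ndarray
    regime: str  # "year-linear" | "emission-linear-early" | "emission-linear-late"
    anchor_years: tuple[int, ...]
    degenerate: np.ndarray = field(default=None)  # cells fit by fallback

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.grid.shape, dtype=bool)


def interp_eq1(dep_1960: AnnualField, dep_1970: AnnualField, year: int) -> AnnualField:
    """Linear-in-year interpolation between the 1960 and 1970 maps."""
    if dep_1960.grid != dep_1970.grid:
        raise ValueError("anchor fields are on different grids")
    if not 1960 < year < 1970:
        raise ValueError(f"interp_eq1 covers 1961-1969 only, got {year}")
    b1 = (dep_1970.values - dep_1960.values) / 10.0
    b0 = dep_1960.values - 1960.0 * b1
    return AnnualField(dep_1960.grid, b0 + b1 * year, units=dep_1960.units, year=year)


def fit_eq2(dep_anchors: dict[int, AnnualField],
            emis_anchors: dict[int, AnnualField],
            regime: str = "emission-linear-early") -> RegressionParams:
    """Per-cell OLS of deposition on emission over common anchor years.

    Cells where emission has zero variance across anchors (or where any
    anchor is missing) are flagged degenerate; their intercept is set to the
    mean anchor deposition with zero slope, keeping the series continuous
    without inventing a trend.
    """
    years = sorted(set(dep_anchors) & set(emis_anchors))
    if len(years) < 2:
        raise ValueError(f"need >= 2 common anchor years, got {len(years)}")
    g = dep_anchors[years[0]].grid
    for y in years:
        if dep_anchors[y].grid != g or emis_anchors[y].grid != g:
            raise ValueError("anchor fields are on different grids")
    D = np.stack([dep_anchors[y].values for y in years])   # (n, nlat, nlon)
    E = np.stack([emis_anchors[y].values for y in years])
    n = len(years)
    Ebar, Dbar = E.mean(axis=0), D.mean(axis=0)
    Sxx = ((E - Ebar) ** 2).sum(axis=0)
    Sxy = ((E - Ebar) * (D - Dbar)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = Sxy / Sxx
    degenerate = (Sxx <= 0) | ~np.isfinite(b1) | ~np.isfinite(Dbar)
    b1 = np.where(degenerate, 0.0, b1)
    b0 = np.where(degenerate, np.nanmean(D, axis=0), Dbar - b1 * Ebar)
    return RegressionParams(g, b0, b1, regime=regime,
                            anchor_years=tuple(years), degenerate=degenerate)


def predict_eq2(params: RegressionParams, emission: AnnualField,
                clip_negative: bool = True) -> AnnualField:
    """Evaluate the fitted relation at an emission map; clip below zero."""
    if emission.grid != params.grid:
        raise ValueError("emission grid does not match fitted parameters")
    pred = params.beta0 + params.beta1 * emission.values
    if clip_negative:
        pred = np.maximum(pred, 0.0)
    return AnnualField(params.grid, pred, units="kg N ha-1 yr-1", year=emission.year)


@dataclass
class DepositionSeries:
    """Annual deposition fields 1961-2020 with per-year provenance.

    Provenance is one of ``observed-anchor``, ``eq1-interp``, ``eq2-interp``,
    ``eq2-extrap``, ``held``.
    """

    fields: dict[int, AnnualField]
    provenance: dict[int, str]
    n_clipped: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, year: int) -> AnnualField:
        return self.fields[year]

    @property
    def years(self) -> list[int]:
        return sorted(self.fields)


def complete_series(anchors: dict[int, AnnualField],
                    emissions: dict[int, AnnualField],
                    *,
                    early_anchors: tuple[int, ...] = EARLY_ANCHORS,
                    late_anchors: tuple[int, ...] = LATE_ANCHORS,
                    hold_from: int = 2018,
                    clip_negative: bool = True) -> DepositionSeries:
    """Fill the full 1961-2020 deposition series from anchor maps.

    ``anchors`` maps anchor year -> deposition field (must include 1960 plus
    the early and late anchor sets); ``emissions`` maps year -> emission
    field for every non-anchor year between 1971 and ``hold_from``.
    Anchor years pass through unchanged.
    """
    required = {1960, *early_anchors, *late_anchors}
    missing = sorted(required - set(anchors))
    if missing:
        raise ValueError(f"missing required anchor year(s): {missing}")
    grid = anchors[1960].grid

    fields: dict[int, AnnualField] = {}
    prov: dict[int, str] = {}
    n_clipped: dict[int, int] = {}

    fit_early = fit_eq2({y: anchors[y] for y in early_anchors},
                        {y: emissions[y] for y in early_anchors if y in emissions},
                        regime="emission-linear-early") if any(
        y not in anchors for y in range(1971, 1997)) else None
    fit_late = fit_eq2({y: anchors[y] for y in late_anchors},
                       {y: emissions[y] for y in late_anchors if y in emissions},
                       regime="emission-linear-late")

    for year in range(1961, 2021):
        if year in anchors:
            fields[year] = anchors[year]
            prov[year] = "observed-anchor"
            continue
        if year <= 1969:
            fields[year] = interp_eq1(anchors[1960], anchors[1970], year)
            prov[year] = "eq1-interp"
        elif year <= 1996:
            if year not in emissions:
                raise ValueError(f"emission map for year {year} is missing")
            raw = fit_early.beta0 + fit_early.beta1 * emissions[year].values
            n_clipped[year] = int((raw < 0).sum()) if clip_negative else 0
            fields[year] = predict_eq2(fit_early, emissions[year], clip_negative)
            prov[year] = "eq2-interp"
        elif year <= hold_from:
            if year not in emissions:
                raise ValueError(f"emission map for year {year} is missing")
            raw = fit_late.beta0 + fit_late.beta1 * emissions[year].values
            n_clipped[year] = int((raw < 0).sum()) if clip_negative else 0
            fields[year] = predict_eq2(fit_late, emissions[year], clip_negative)
            prov[year] = "eq2-extrap"
        else:
            held = fields[hold_from]
            fields[year] = AnnualField(grid, held.values.copy(), units=held.units, year=year)
            prov[year] = "held"
    return DepositionSeries(fields, prov, n_clipped)
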