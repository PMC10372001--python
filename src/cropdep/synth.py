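"""Synthetic world generator with known ground truth.

Produces self-contained inputs mimicking the statistical shape of the real
pipeline inputs — a smooth deposition field with a per-cell linear temporal
trend, an emission field exactly (or noisily) affine to deposition per cell,
five cropland sub-type fraction fields on a nested finer grid, a block
country mask, station daily records, and budget tables with known NUE —
plus the ground-truth national table computed by an independent direct
per-cell loop, not by the pipeline under test.

Deposition truth is linear in year per cell up to 2018 and held constant for
2019-2020 (mirroring the hold rule), so a noise-free world is exactly
recoverable by the gap-filling regressions.  All randomness derives from one
seed through named spawned substreams, so each component's draws are
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cropland import LUH2_CROP_TYPES, CroplandSeries, build_cropland_series
from .gapfill import WANG_ANCHOR_PATTERN, DepositionSeries
from .grid import AnnualField, CountryMask, GridSpec

YEARS = tuple(range(1961, 2021))
EMISSION_YEARS = tuple(range(1970, 2019))


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    The coarse grid carries deposition and emission; the cropland fraction
    grid is ``refine`` times finer and nests exactly.  Per-cell deposition is
    ``base + trend * (year - 1990)`` (kg N ha-1 yr-1, kept positive by
    construction), and emission is exactly ``(dep - a) / b`` per cell, so
    deposition is exactly affine in emission.  ``sigma`` is the s.d. of
    Gaussian observation noise added to the *observed anchor deposition
    maps* (the regressand of the gap-filling regressions); the truth series
    stays clean, so slope estimates remain unbiased under noise.
    """

    nlat: int = 20
    nlon: int = 40
    refine: int = 4
    n_countries: int = 8
    sigma: float = 0.0
    anchor_pattern: tuple[int, ...] = WANG_ANCHOR_PATTERN
    seed: int = 0
    lat_span: tuple[float, float] = (-60.0, 60.0)
    lon_span: tuple[float, float] = (-180.0, 180.0)
    base_rate: float = 12.0        # mean deposition level, kg N ha-1 yr-1
    trend_scale: float = 0.08      # s.d. of per-cell trend, kg N ha-1 yr-2
    spatial_amplitude: float = 0.4  # relative amplitude of the smooth base field

    def __post_init__(self):
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.refine < 1 or int(self.refine) != self.refine:
            raise ValueError("cropland grid must nest: refine must be a positive integer")


@dataclass
class World:
    """Generated bundle: inputs for the pipeline plus withheld ground truth."""

    config: WorldConfig
    grid: GridSpec
    fine_grid: GridSpec
    deposition_truth: DepositionSeries
    emissions: dict[int, AnnualField]
    cropland_fractions: dict[int, dict[str, AnnualField]]
    cropland_series: CroplandSeries
    mask: CountryMask
    truth_rates: pd.DataFrame        # country x year, kg N ha-1 yr-1
    truth_totals: pd.DataFrame       # country x year, Tg N yr-1
    budget: pd.DataFrame = None
    stations: pd.DataFrame = None
    nue_truth: pd.DataFrame = None
    station_target_flux: dict = field(default_factory=dict)
    observed_anchors: dict = field(default_factory=dict)  # year -> (noisy) anchor field


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _harmonic_field(grid: GridSpec, rng: np.random.Generator,
                    n_modes: int = 3, amplitude: float = 1.0) -> np.ndarray:
    """Smooth random field from a few low-order lat/lon harmonics."""
    lat = np.radians(grid.lat_centers)[:, None]
    lon = np.radians(grid.lon_centers)[None, :]
    out = np.zeros(grid.shape)
    for _ in range(n_modes):
        kl, km = rng.integers(1, 4, size=2)
        pl, pm = rng.uniform(0, 2 * np.pi, size=2)
        out += rng.normal(0, amplitude) * np.cos(kl * lat * 2 + pl) * np.cos(km * lon + pm)
    return out / max(n_modes, 1)


def _block_mask(grid: GridSpec, n_countries: int) -> CountryMask:
    """Contiguous lat/lon blocks with exact 0/1 shares; some cells left
    unclaimed as 'ocean' (the last lon column)."""
    codes = [f"C{k:03d}" for k in range(n_countries)]
    shares = np.zeros((n_countries, grid.nlat, grid.nlon))
    ocean_cols = max(1, grid.nlon // 10)
    usable = grid.nlon - ocean_cols
    # split countries across a near-square arrangement of blocks
    nrows = int(np.floor(np.sqrt(n_countries))) or 1
    ncols = int(np.ceil(n_countries / nrows))
    lat_bounds = np.linspace(0, grid.nlat, nrows + 1).astype(int)
    lon_bounds = np.linspace(0, usable, ncols + 1).astype(int)
    for k in range(n_countries):
        r, c = divmod(k, ncols)
        shares[k, lat_bounds[r]:lat_bounds[r + 1], lon_bounds[c]:lon_bounds[c + 1]] = 1.0
    return CountryMask(grid, codes, shares)


def _fine_cell_band_areas_ha(fine: GridSpec) -> np.ndarray:
    """Independent spherical band areas (ha) per fine-lat row, coded directly
    from the bounded-by-parallels formula so truth does not reuse grid.cell_areas."""
    R = 6_371_000.0
    edges = np.radians(fine.lat_edges)
    dlon = np.radians(fine.lon_step)
    return R * R * dlon * (np.sin(edges[1:]) - np.sin(edges[:-1])) / 1e4


def generate_world(config: WorldConfig) -> World:
    """Build the full synthetic bundle; deterministic given ``config.seed``."""
    cfg = config
    rngs = _rngs(cfg.seed, ["base", "trend", "affine", "noise", "cropland",
                            "stations", "budget"])

    lat0, lat1 = cfg.lat_span
    lon0, lon1 = cfg.lon_span
    dlat, dlon = (lat1 - lat0) / cfg.nlat, (lon1 - lon0) / cfg.nlon
    grid = GridSpec(lat0 + dlat * (np.arange(cfg.nlat) + 0.5),
                    lon0 + dlon * (np.arange(cfg.nlon) + 0.5))
    f = cfg.refine
    fine = GridSpec(lat0 + dlat / f * (np.arange(cfg.nlat * f) + 0.5),
                    lon0 + dlon / f * (np.arange(cfg.nlon * f) + 0.5))

    # --- deposition truth: base + trend*(year-1990), held after 2018 ---
    base = cfg.base_rate * (1.0 + cfg.spatial_amplitude * _harmonic_field(grid, rngs["base"]))
    base = np.clip(base, 1.0, None)
    trend = cfg.trend_scale * (_harmonic_field(grid, rngs["trend"]) +
                               0.5 * rngs["trend"].standard_normal(grid.shape))
    # keep deposition positive across 1960-2020 so the clip never bites truth
    span = np.abs(trend) * 30.0
    base = np.maximum(base, span + 0.5)

    def dep_at(year: int) -> np.ndarray:
        yy = min(year, 2018)
        return base + trend * (yy - 1990)

    dep_fields = {y: AnnualField(grid, dep_at(y), units="kg N ha-1 yr-1", year=y)
                  for y in range(1960, 2021)}
    # 1960 is carried as the anchor source even though the product series
    # itself spans 1961-2020
    truth = DepositionSeries({y: dep_fields[y] for y in range(1960, 2021)},
                             {y: "truth" for y in range(1960, 2021)})

    # --- emission exactly affine to deposition per cell: dep = a + b*emis ---
    a = rngs["affine"].uniform(-2.0, 2.0, size=grid.shape)
    b = rngs["affine"].uniform(0.5, 2.0, size=grid.shape)
    emissions = {y: AnnualField(grid, (dep_at(y) - a) / b, units="kg N", year=y)
                 for y in EMISSION_YEARS}

    # observed anchor maps: truth plus (optional) Gaussian observation noise
    observed_anchors = {}
    for y in cfg.anchor_pattern:
        if cfg.sigma > 0:
            noisy = dep_at(y) + rngs["noise"].normal(0.0, cfg.sigma, size=grid.shape)
            observed_anchors[y] = AnnualField(grid, noisy, units="kg N ha-1 yr-1", year=y)
        else:
            observed_anchors[y] = dep_fields[y]  # bit-equal passthrough

    # --- cropland: five sub-type fractions on the fine grid, fixed in time ---
    fracs = {}
    for t in LUH2_CROP_TYPES:
        raw = 0.25 * (1 + _harmonic_field(fine, rngs["cropland"], amplitude=0.8))
        fracs[t] = AnnualField(fine, np.clip(raw, 0.0, 1.0), units="1")
    luh2_years = {y: fracs for y in range(1961, 2016)}
    cropland = build_cropland_series(luh2_years, grid, source="luh2")

    mask = _block_mask(grid, cfg.n_countries)

    # --- independent ground-truth national aggregation (direct loops) ---
    frac_stack = np.stack([fracs[t].values for t in LUH2_CROP_TYPES])
    max_frac = frac_stack.max(axis=0)
    band = _fine_cell_band_areas_ha(fine)
    fine_area = max_frac * band[:, None]          # ha per fine cell
    # block-sum fine areas to the coarse grid (grids nest exactly)
    crop_coarse = fine_area.reshape(cfg.nlat, f, cfg.nlon, f).sum(axis=(1, 3))

    rates = np.full((cfg.n_countries, len(YEARS)), np.nan)
    totals = np.zeros((cfg.n_countries, len(YEARS)))
    for yi, y in enumerate(YEARS):
        d = dep_at(y)
        for k in range(cfg.n_countries):
            num = den = 0.0
            for i in range(cfg.nlat):
                for j in range(cfg.nlon):
                    w = crop_coarse[i, j] * mask.shares[k, i, j]
                    num += d[i, j] * w
                    den += w
            if den > 0:
                rates[k, yi] = num / den
                totals[k, yi] = num * 1e-9
    idx = pd.Index(mask.countries, name="country")
    truth_rates = pd.DataFrame(rates, index=idx, columns=list(YEARS))
    truth_totals = pd.DataFrame(totals, index=idx, columns=list(YEARS))

    # --- station records: daily draws annualizing to known targets ---
    # three stations per country bracket the national truth rate (0.8x, 1x,
    # 1.2x), giving each country a non-degenerate station spread
    station_rows, targets = [], {}
    for k, code in enumerate(mask.countries):
        national = float(truth_rates.iloc[k][2000])
        if not np.isfinite(national):
            national = 10.0
        for s_i, mult in enumerate((0.8, 1.0, 1.2)):
            sid = f"S{k:02d}{chr(ord('a') + s_i)}"
            target = national * mult
            targets[sid] = target
            n_days = int(rngs["stations"].integers(60, 200))
            days = rngs["stations"].choice(365, size=n_days, replace=False)
            precip = rngs["stations"].uniform(1.0, 20.0, size=n_days)
            conc = (target / 365.0) / (0.01 * precip)   # constant daily flux
            for d, p, c in zip(np.sort(days), precip, conc):
                station_rows.append({
                    "station_id": sid, "country": code,
                    "date": (pd.Timestamp("2000-01-01") + pd.Timedelta(days=int(d))).date().isoformat(),
                    "lat": 0.0, "lon": 0.0,
                    "total_n_mg_per_l": c, "precip_mm": p,
                })
    stations = pd.DataFrame(station_rows)

    # --- budget tables with known NUE ---
    nue_target = rngs["budget"].uniform(0.4, 0.8, size=(cfg.n_countries, len(YEARS)))
    rows = []
    for k, code in enumerate(mask.countries):
        for yi, y in enumerate(YEARS):
            ad = totals[k, yi] * 1e9  # Tg -> kg N
            sf = rngs["budget"].uniform(1e9, 5e9)
            mn = rngs["budget"].uniform(1e8, 1e9)
            bnf = rngs["budget"].uniform(1e8, 5e8)
            cr = nue_target[k, yi] * (sf + mn + bnf + ad)
            rows.append({"country": code, "year": y, "n_cr": cr, "n_sf": sf,
                         "n_mn": mn, "n_bnf": bnf,
                         "n_ad_ah": ad, "n_ad_al": ad, "n_ad_wh": ad, "n_ad_wl": ad})
    budget = pd.DataFrame(rows)
    nue_truth = pd.DataFrame(nue_target, index=idx, columns=list(YEARS))

    return World(cfg, grid, fine, truth, emissions, {0: fracs}, cropland, mask,
                 truth_rates, truth_totals, budget, stations, nue_truth, targets,
                 observed_anchors)


def degrade_to_anchors(truth: DepositionSeries,
                       pattern=WANG_ANCHOR_PATTERN) -> dict[int, AnnualField]:
    """Keep only the anchor-pattern years of a full deposition series.

    The withheld years become the recovery test set.  Retained fields are
    the same objects (bit-equal passthrough).
    """
    pattern = tuple(pattern)
    if not pattern:
        raise ValueError("anchor pattern must not be empty")
    missing = [y for y in pattern if y not in truth.fields]
    if missing:
        raise ValueError(f"pattern years absent from truth: {missing}")
    return {y: truth.fields[y] for y in pattern}
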