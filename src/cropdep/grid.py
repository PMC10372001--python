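"""Regular lat/lon grid model, spherical cell areas, conservative regridding,
and country-mask construction.

All grids are rectilinear with uniform spacing in latitude and longitude.
Cell "area" is true spherical area on a sphere of radius 6371 km, so that
hectare and teragram bookkeeping downstream is physically meaningful.
Longitudes are normalized to [-180, 180); latitude axes are stored ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_000.0  # mean spherical radius

#: unit labels accepted on AnnualField and whether each is extensive
#: (summable mass/area over cells) or intensive (a per-area rate).
UNIT_KIND = {
    "kg N ha-1 yr-1": "intensive",
    "kg N ha-1 day-1": "intensive",
    "ha": "extensive",
    "kg N": "extensive",
    "1": "intensive",  # dimensionless fraction
}


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid defined by its cell-center coordinates.

    Parameters
    ----------
    lat_centers, lon_centers
        1-D arrays of cell-center coordinates in degrees.  Spacing must be
        uniform to 1e-9 deg.  Latitude edges must stay inside [-90, 90];
        the longitude span must not exceed 360 deg.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size == 0 or lon.size == 0:
            raise ValueError("lat_centers and lon_centers must be non-empty 1-D arrays")
        # normalize: ascending latitude, longitudes wrapped to [-180, 180)
        if lat.size > 1 and lat[1] < lat[0]:
            lat = lat[::-1]
        lon = ((lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        for name, c in (("lat", lat), ("lon", lon)):
            if c.size > 1:
                steps = np.diff(self._unwrapped(c) if name == "lon" else c)
                if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                    raise ValueError(f"{name} spacing is not uniform")
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise ValueError("grid steps must be positive")
        edges = self.lat_edges
        if edges[0] < -90.0 - 1e-9 or edges[-1] > 90.0 + 1e-9:
            raise ValueError("latitude cell edges extend past the poles")
        if self.lon_step * lon.size > 360.0 + 1e-9:
            raise ValueError("longitude span exceeds 360 degrees")

    @staticmethod
    def _unwrapped(lon: np.ndarray) -> np.ndarray:
        """Monotonic version of a wrapped longitude axis."""
        out = lon.astype(float).copy()
        for i in range(1, out.size):
            while out[i] <= out[i - 1]:
                out[i] += 360.0
        return out

    @property
    def nlat(self) -> int:
        return self.lat_centers.size

    @property
    def nlon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lat_step(self) -> float:
        if self.lat_centers.size > 1:
            return float(self.lat_centers[1] - self.lat_centers[0])
        return float(2 * min(self.lat_centers[0] + 90.0, 90.0 - self.lat_centers[0])) or 180.0

    @property
    def lon_step(self) -> float:
        if self.lon_centers.size > 1:
            u = self._unwrapped(self.lon_centers)
            return float(u[1] - u[0])
        return 360.0

    @property
    def lat_edges(self) -> np.ndarray:
        c, s = self.lat_centers, self.lat_step
        return np.concatenate([c - s / 2.0, [c[-1] + s / 2.0]])

    @property
    def lon_edges(self) -> np.ndarray:
        """Monotonic longitude edges (unwrapped; may exceed 180)."""
        u = self._unwrapped(self.lon_centers)
        s = self.lon_step
        return np.concatenate([u - s / 2.0, [u[-1] + s / 2.0]])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GridSpec)
            and np.array_equal(self.lat_centers, other.lat_centers)
            and np.array_equal(self.lon_centers, other.lon_centers)
        )

    def __hash__(self):
        return hash((self.lat_centers.tobytes(), self.lon_centers.tobytes()))


@dataclass
class AnnualField:
    """One year of a gridded quantity with declared units.

    ``values`` has shape ``grid.shape`` (lat, lon); NaN marks missing cells.
    Fraction fields must lie in [0, 1]; area fields must be non-negative.
    """

    grid: GridSpec
    values: np.ndarray
    units: str
    year: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.units not in UNIT_KIND:
            raise ValueError(f"unknown units {self.units!r}; expected one of {sorted(UNIT_KIND)}")
        finite = self.values[np.isfinite(self.values)]
        if self.units == "1" and finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("fraction field has values outside [0, 1]")
        if self.units == "ha" and finite.size and finite.min() < -1e-12:
            raise ValueError("area field has negative values")

    @property
    def is_extensive(self) -> bool:
        return UNIT_KIND[self.units] == "extensive"


def cell_areas(grid: GridSpec) -> AnnualField:
    """Spherical area of every grid cell, in hectares.

    Each cell is a spherical quadrilateral bounded by meridians and
    parallels; its area is ``R^2 * dlon * (sin(lat_top) - sin(lat_bot))``,
    independent of longitude.
    """
    edges = np.radians(grid.lat_edges)
    dlon = np.radians(grid.lon_step)
    band = EARTH_RADIUS_M**2 * dlon * np.diff(np.sin(edges))  # m^2 per cell, by lat band
    areas = np.repeat(band[:, None], grid.nlon, axis=1) / 1e4  # -> ha
    return AnnualField(grid, areas, units="ha")


def _axis_overlap(fine_edges: np.ndarray, coarse_edges: np.ndarray,
                  weight_fn=None, periodic: bool = False) -> np.ndarray:
    """Fractional overlap matrix W[coarse, fine]: the fraction of each fine
    interval's measure that falls inside each coarse interval.

    ``weight_fn`` maps edge coordinates to the measure coordinate (identity
    for longitude, sin(lat) for latitude so that fractions are area-true).
    With ``periodic`` the fine intervals are also tried shifted by +-360.
    """
    if weight_fn is None:
        weight_fn = lambda x: x
    shifts = (0.0, 360.0, -360.0) if periodic else (0.0,)
    nf, nc = fine_edges.size - 1, coarse_edges.size - 1
    W = np.zeros((nc, nf))
    for j in range(nf):
        m_fine = weight_fn(fine_edges[j + 1]) - weight_fn(fine_edges[j])
        if m_fine <= 0:
            continue
        for shift in shifts:
            lo, hi = fine_edges[j] + shift, fine_edges[j + 1] + shift
            i0 = np.searchsorted(coarse_edges, lo, side="right") - 1
            i1 = np.searchsorted(coarse_edges, hi, side="left")
            for i in range(max(i0, 0), min(i1, nc)):
                a, b = max(lo, coarse_edges[i]), min(hi, coarse_edges[i + 1])
                if b > a:
                    W[i, j] += (weight_fn(b) - weight_fn(a)) / m_fine
    return W


def regrid_sum(fine: AnnualField, coarse_grid: GridSpec) -> AnnualField:
    """Conservatively aggregate an extensive field to a coarser grid.

    Each coarse cell receives the sum of fine-cell values apportioned by
    fractional spherical overlap; the global total is conserved.  Intensive
    fields (rates, fractions) are rejected: summing a rate is meaningless.

    Missing (NaN) fine cells contribute zero unless *every* fine cell
    overlapping a coarse cell is missing, in which case the coarse cell is
    missing.
    """
    if not fine.is_extensive:
        raise ValueError(
            f"regrid_sum requires an extensive quantity; got units {fine.units!r} "
            "(rates and fractions must be converted to areas/masses first)"
        )
    fg = fine.grid
    if fg.lat_step > coarse_grid.lat_step + 1e-12 or fg.lon_step > coarse_grid.lon_step + 1e-12:
        raise ValueError("fine grid must be strictly finer than the coarse grid")
    sinlat = np.sin
    Wlat = _axis_overlap(np.radians(fg.lat_edges), np.radians(coarse_grid.lat_edges),
                         weight_fn=sinlat)
    Wlon = _axis_overlap(fg.lon_edges, coarse_grid.lon_edges, periodic=True)
    vals = np.nan_to_num(fine.values, nan=0.0)
    out = Wlat @ vals @ Wlon.T
    # missing only where no finite fine cell contributes
    contrib = Wlat @ np.isfinite(fine.values).astype(float) @ Wlon.T
    covered = (Wlat @ np.ones(fg.shape) @ Wlon.T) > 1e-12
    out[covered & (contrib <= 1e-12)] = np.nan
    return AnnualField(coarse_grid, out, units=fine.units, year=fine.year)


@dataclass
class CountryMask:
    """Per-cell fractional membership of grid cells in countries.

    ``shares`` has shape ``(n_countries, nlat, nlon)``; per-cell sums may be
    below 1 (ocean / unclaimed area) but never above.
    """

    grid: GridSpec
    countries: list[str]
    shares: np.ndarray

    def __post_init__(self):
        self.shares = np.asarray(self.shares, dtype=float)
        if self.shares.shape != (len(self.countries),) + self.grid.shape:
            raise ValueError("shares shape must be (n_countries, nlat, nlon)")
        if self.shares.min() < -1e-12 or self.shares.max() > 1 + 1e-9:
            raise ValueError("shares must lie in [0, 1]")
        totals = self.shares.sum(axis=0)
        if totals.max() > 1 + 1e-9:
            raise ValueError("per-cell country shares exceed 1 (overlapping claims)")

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    def majority(self) -> "CountryMask":
        """Whole-cell assignment: each cell goes entirely to the country with
        the largest share (ties to the first in list order); cells with no
        claim stay unassigned."""
        hard = np.zeros_like(self.shares)
        tot = self.shares.sum(axis=0)
        winner = self.shares.argmax(axis=0)
        ii, jj = np.nonzero(tot > 1e-12)
        hard[winner[ii, jj], ii, jj] = 1.0
        return CountryMask(self.grid, list(self.countries), hard)


def rasterize_countries(polygons: dict[str, "object"] | Sequence[tuple[str, "object"]],
                        grid: GridSpec) -> CountryMask:
    """Fractional rasterization of country polygons onto a grid.

    ``polygons`` maps ISO3 code -> shapely geometry in lon/lat degrees.
    The share of a cell assigned to a country is the polygon/cell overlap
    area in degree coordinates divided by the cell's degree area.  Polygons
    jointly claiming more than 100% of any cell raise an error.
    """
    from shapely.geometry import box
    from shapely.validation import explain_validity

    items = list(polygons.items()) if isinstance(polygons, dict) else list(polygons)
    codes = [c for c, _ in items]
    shares = np.zeros((len(items), grid.nlat, grid.nlon))
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    cell_deg_area = grid.lat_step * grid.lon_step
    for k, (code, geom) in enumerate(items):
        if not geom.is_valid:
            raise ValueError(f"polygon for {code} is invalid: {explain_validity(geom)}")
        gminx, gminy, gmaxx, gmaxy = geom.bounds
        for i in range(grid.nlat):
            if lat_e[i + 1] < gminy or lat_e[i] > gmaxy:
                continue
            for j in range(grid.nlon):
                for shift in (0.0, 360.0, -360.0):
                    x0, x1 = lon_e[j] + shift, lon_e[j + 1] + shift
                    if x1 < gminx or x0 > gmaxx:
                        continue
                    cell = box(x0, lat_e[i], x1, lat_e[i + 1])
                    inter = geom.intersection(cell)
                    if not inter.is_empty:
                        shares[k, i, j] += inter.area / cell_deg_area
    shares = np.clip(shares, 0.0, 1.0)
    return CountryMask(grid, codes, shares)


def mask_from_codes(code_grid: np.ndarray, grid: GridSpec,
                    codes: Sequence[str] | None = None) -> CountryMask:
    """Build a 0/1 CountryMask from a pre-rasterized integer code grid.

    ``code_grid`` holds per-cell integer country ids (<0 = no country);
    ``codes`` maps id -> ISO3 label (defaults to ``C000``, ``C001``, ...).
    """
    code_grid = np.asarray(code_grid)
    if code_grid.shape != grid.shape:
        raise ValueError("code grid shape does not match grid")
    ids = sorted(int(v) for v in np.unique(code_grid) if v >= 0)
    labels = [codes[i] if codes is not None else f"C{i:03d}" for i in ids]
    shares = np.stack([(code_grid == i).astype(float) for i in ids])
    return CountryMask(grid, labels, shares)
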