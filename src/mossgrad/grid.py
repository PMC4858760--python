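"""Spatial data model: equal-area lattice, occurrence rasterization, species
incidence matrices, region splitting and map correlation.

Conventions (fixed across the whole package):

* 2-D per-pixel arrays have shape ``(n_rows, n_cols)`` and are stored
  row-major from the **north-west** corner, i.e. row 0 is the northernmost
  row.  ESRI ASCII grids use the same row order, so I/O is a straight copy.
* Per-pixel *vectors* (richness, environmental layers, species occupancy
  rows) are the row-major flattening of the 2-D grid restricted to land
  pixels, in that same order.
* Pixel membership uses half-open intervals ``[x0, x0+s) x [y0, y0+s)``:
  a point on a pixel boundary belongs to the pixel on its lower-left.
* Ocean / NODATA pixels are excluded from every statistic, never
  zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "LatticeGrid",
    "SpeciesGrid",
    "RegionMask",
    "RichnessMap",
    "CorrelationResult",
    "read_occurrences",
    "rasterize",
    "filter_min_presence",
    "split_regions",
    "map_correlation",
    "richness_from_occupancy",
]


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeGrid:
    """Equal-area pixel lattice.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; row 0 is the northernmost row.
    pixel_size
        Pixel edge length in projected units (km; nominally 100).
    origin
        ``(x, y)`` of the lower-left corner of the grid in projected
        equal-area coordinates (same units as ``pixel_size``).
    land_mask
        Boolean ``(n_rows, n_cols)`` array; True marks land pixels.
    row_lat
        Centroid latitude (decimal degrees) of each row, row 0 first.
        Must be monotone (decreasing from north to south).
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    origin: tuple[float, float]
    land_mask: np.ndarray
    row_lat: np.ndarray

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        land = np.asarray(self.land_mask, dtype=bool)
        if land.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"land_mask shape {land.shape} != ({self.n_rows}, {self.n_cols})"
            )
        lat = np.asarray(self.row_lat, dtype=float)
        if lat.shape != (self.n_rows,):
            raise ValueError("row_lat must have one entry per row")
        d = np.diff(lat)
        if not (np.all(d <= 0) or np.all(d >= 0)):
            raise ValueError("row_lat must be monotone across rows")
        object.__setattr__(self, "land_mask", land)
        object.__setattr__(self, "row_lat", lat)

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        pixel_size: float = 100.0,
        origin: tuple[float, float] = (0.0, 0.0),
        lat_range: tuple[float, float] = (40.0, 52.0),
        land_mask: np.ndarray | None = None,
    ) -> "LatticeGrid":
        """Lattice with row latitudes linear in projected northing.

        ``lat_range`` gives (southern edge, northern edge) latitude of the
        grid; row centroids are placed accordingly.
        """
        lat_s, lat_n = lat_range
        if land_mask is None:
            land_mask = np.ones((n_rows, n_cols), dtype=bool)
        # row r centroid sits (r + 0.5) pixel below the northern edge
        frac = (np.arange(n_rows) + 0.5) / n_rows
        row_lat = lat_n - frac * (lat_n - lat_s)
        return cls(n_rows, n_cols, float(pixel_size), origin, land_mask, row_lat)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @property
    def land_rc(self) -> np.ndarray:
        """(n_land, 2) array of (row, col) indices, row-major order."""
        return np.argwhere(self.land_mask)

    @property
    def land_flat_index(self) -> np.ndarray:
        """Row-major flat index of each land pixel within the full grid."""
        return np.flatnonzero(self.land_mask.ravel())

    def row_northing(self, rows: np.ndarray) -> np.ndarray:
        """Projected northing (y) of row centroids."""
        x0, y0 = self.origin
        return y0 + (self.n_rows - np.asarray(rows) - 0.5) * self.pixel_size

    @property
    def centroid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected centroid coordinates of land pixels."""
        rc = self.land_rc
        x0, y0 = self.origin
        x = x0 + (rc[:, 1] + 0.5) * self.pixel_size
        y = self.row_northing(rc[:, 0])
        return x, y

    @property
    def centroid_lat(self) -> np.ndarray:
        """Centroid latitude (degrees) of each land pixel."""
        return self.row_lat[self.land_rc[:, 0]]

    # -- point-in-pixel -----------------------------------------------------

    def locate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projected points to (row, col); -1 where outside the grid.

        Half-open convention: a point on a shared edge belongs to the pixel
        on its lower-left.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.pixel_size).astype(int)
        row_from_bottom = np.floor((y - y0) / self.pixel_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def land_index_lookup(self) -> np.ndarray:
        """Full-grid (n_rows, n_cols) int array: land-vector position of each
        pixel, or -1 for ocean."""
        lut = np.full((self.n_rows, self.n_cols), -1, dtype=int)
        rc = self.land_rc
        lut[rc[:, 0], rc[:, 1]] = np.arange(self.n_land)
        return lut

    def to_full(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a land-pixel vector back onto the full 2-D grid."""
        values = np.asarray(values)
        out = np.full((self.n_rows, self.n_cols), fill, dtype=float)
        rc = self.land_rc
        out[rc[:, 0], rc[:, 1]] = values
        return out


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("species", "x", "y")


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence table (CSV with columns ``species,x,y[,group]``).

    Returns a DataFrame with string species labels and float coordinates.
    Malformed rows raise :class:`FormatError` naming the offending file
    lines (1-based, header = line 1).  A file with only a header yields an
    empty table.
    """
    try:
        df = pd.read_csv(path, dtype={"species": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header row)")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return df.loc[:, list(df.columns)]
    for c in ("x", "y"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() | ~np.isfinite(coerced.fillna(np.inf))
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric or non-finite '{c}' on line(s) {lines}"
            )
        df[c] = coerced.astype(float)
    empty_sp = df["species"].isna() | (df["species"].str.strip() == "")
    if empty_sp.any():
        lines = (df.index[empty_sp] + 2).tolist()
        raise FormatError(f"{path}: empty species label on line(s) {lines}")
    return df


# ---------------------------------------------------------------------------
# species incidence
# ---------------------------------------------------------------------------

@dataclass
class SpeciesGrid:
    """Presence/absence matrix over the land pixels of a lattice.

    ``occupancy`` has shape ``(n_land, n_species)`` (bool) with rows in the
    grid's land-pixel order and columns matching ``species_ids``.
    """

    grid: LatticeGrid
    species_ids: list[str]
    occupancy: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (self.grid.n_land, len(self.species_ids)):
            raise ValueError(
                f"occupancy shape {occ.shape} != "
                f"({self.grid.n_land}, {len(self.species_ids)})"
            )
        self.occupancy = occ
        self.species_ids = [str(s) for s in self.species_ids]

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def presence_counts(self) -> np.ndarray:
        """Number of occupied pixels per species."""
        return self.occupancy.sum(axis=0)

    # -- round-trip serialization (wide CSV) --------------------------------

    def to_wide_csv(self, path) -> None:
        df = pd.DataFrame(
            self.occupancy.astype(int),
            index=pd.Index(self.grid.land_flat_index, name="pixel_id"),
            columns=self.species_ids,
        )
        df.to_csv(path)

    @classmethod
    def from_wide_csv(cls, path, grid: LatticeGrid) -> "SpeciesGrid":
        df = pd.read_csv(path, index_col="pixel_id")
        expected = grid.land_flat_index
        if not np.array_equal(df.index.to_numpy(), expected):
            raise FormatError(f"{path}: pixel_id column does not match the grid")
        return cls(grid, list(df.columns), df.to_numpy(dtype=bool))


def rasterize(occ: pd.DataFrame, grid: LatticeGrid) -> SpeciesGrid:
    """Bin occurrence records onto the lattice: a pixel-species cell is
    present iff at least one record falls inside it.

    Records outside the grid or on ocean pixels are counted in
    ``result.meta['n_outside']`` / ``meta['n_ocean']`` and logged, never
    silently dropped.
    """
    species_ids = sorted(occ["species"].unique()) if len(occ) else []
    sp_index = {s: k for k, s in enumerate(species_ids)}
    occupancy = np.zeros((grid.n_land, len(species_ids)), dtype=bool)
    n_outside = n_ocean = 0
    if len(occ):
        row, col = grid.locate(occ["x"].to_numpy(), occ["y"].to_numpy())
        lut = grid.land_index_lookup()
        for r, c, s in zip(row, col, occ["species"]):
            if r < 0:
                n_outside += 1
                continue
            li = lut[r, c]
            if li < 0:
                n_ocean += 1
                continue
            occupancy[li, sp_index[s]] = True
    if n_outside or n_ocean:
        logger.warning(
            "rasterize: %d record(s) outside the grid, %d on ocean pixels",
            n_outside, n_ocean,
        )
    return SpeciesGrid(
        grid, species_ids, occupancy,
        meta={"n_records": len(occ), "n_outside": n_outside, "n_ocean": n_ocean},
    )


def filter_min_presence(sg: SpeciesGrid, min_presences: int = 15) -> SpeciesGrid:
    """Retain species occupying at least ``min_presences`` pixels.

    The default of 15 is the conventional lower limit below which
    distribution models are not attempted.
    """
    if min_presences < 1:
        raise ValueError("min_presences must be >= 1")
    counts = sg.presence_counts()
    keep = counts >= min_presences
    removed = [s for s, k in zip(sg.species_ids, keep) if not k]
    if removed:
        logger.info(
            "filter_min_presence(%d): removed %d species: %s",
            min_presences, len(removed), ", ".join(removed[:20]),
        )
    return SpeciesGrid(
        sg.grid,
        [s for s, k in zip(sg.species_ids, keep) if k],
        sg.occupancy[:, keep],
        meta={**sg.meta, "removed_species": removed,
              "min_presences": min_presences},
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMask:
    """North/south partition of land pixels by centroid latitude."""

    grid: LatticeGrid
    is_north: np.ndarray  # (n_land,) bool
    split_latitude: float

    def side(self, name: Literal["north", "south"]) -> np.ndarray:
        """Land-pixel indices of one side."""
        if name == "north":
            return np.flatnonzero(self.is_north)
        if name == "south":
            return np.flatnonzero(~self.is_north)
        raise ValueError(f"unknown region side {name!r}")

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.is_north, "north", "south")


def split_regions(grid: LatticeGrid, split_latitude: float = 46.0) -> RegionMask:
    """Partition land pixels into north (centroid latitude strictly above the
    split parallel) and south (everything else)."""
    is_north = grid.centroid_lat > split_latitude
    if is_north.all() or (~is_north).all():
        logger.warning(
            "split_regions: every land pixel falls on one side of %.2f deg; "
            "regional comparisons will be impossible", split_latitude,
        )
    return RegionMask(grid, is_north, float(split_latitude))


# ---------------------------------------------------------------------------
# richness maps & correlation
# ---------------------------------------------------------------------------

@dataclass
class RichnessMap:
    """Per-land-pixel species richness (integer when stacked from binary
    maps, real when averaged)."""

    grid: LatticeGrid
    richness: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.richness, dtype=float)
        if r.shape != (self.grid.n_land,):
            raise ValueError("richness must be a land-pixel vector")
        if np.nanmin(r) < 0:
            raise ValueError("richness must be non-negative")
        self.richness = r


def richness_from_occupancy(sg: SpeciesGrid) -> RichnessMap:
    """Observed richness: number of species recorded in each pixel."""
    return RichnessMap(sg.grid, sg.occupancy.sum(axis=1).astype(float))


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    method: str


def map_correlation(
    a: RichnessMap,
    b: RichnessMap,
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationResult:
    """Correlation between two richness maps over jointly valid land pixels."""
    if a.grid is not b.grid and (
        a.grid.n_rows != b.grid.n_rows or a.grid.n_cols != b.grid.n_cols
        or not np.array_equal(a.grid.land_mask, b.grid.land_mask)
    ):
        raise ValueError("richness maps are not on the same grid")
    va, vb = a.richness, b.richness
    ok = np.isfinite(va) & np.isfinite(vb)
    n = int(ok.sum())
    if n < 3:
        raise UndefinedStatisticError("fewer than 3 jointly valid pixels")
    va, vb = va[ok], vb[ok]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedStatisticError("zero variance in one of the maps")
    if method == "pearson":
        r = stats.pearsonr(va, vb).statistic
    elif method == "spearman":
        r = stats.spearmanr(va, vb).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(r), n, method)
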