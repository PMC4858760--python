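"""Plain-text raster I/O: ESRI ASCII grids (.asc).

The format is a six-line header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by nrows lines of ncols values, first line
= northernmost row — the same row order the package uses internally, so no
flipping is needed.  NODATA cells are read as NaN and honoured as an ocean
mask.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .grid import LatticeGrid, RichnessMap

__all__ = ["read_asc", "write_asc", "grid_from_asc", "write_richness_asc",
           "read_richness_asc"]

_NODATA = -9999.0


def read_asc(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns ``(values, header)`` where ``values`` is a float
    ``(nrows, ncols)`` array with NaN at NODATA cells and ``header`` carries
    ``ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value``.
    """
    header: dict = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            key = parts[0].lower()
            header[key] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing ASCII-grid header field {req}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        data = np.loadtxt(lines[i:], ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed data block: {exc}") from exc
    if data.size != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} values, found {data.size}"
        )
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header


def write_asc(path, values: np.ndarray, origin: tuple[float, float],
              cellsize: float, nodata: float = _NODATA) -> None:
    """Write a 2-D array (row 0 = north) as an ESRI ASCII grid; NaN cells
    become NODATA."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def grid_from_asc(path, lat_range: tuple[float, float] = (40.0, 52.0)
                  ) -> tuple[LatticeGrid, np.ndarray]:
    """Build a lattice from an ASCII grid; NODATA defines the ocean mask.

    Latitudes are not stored in the .asc format, so row latitudes are
    assigned linearly over ``lat_range`` (southern edge, northern edge).
    Returns ``(grid, land_values)`` with the raster's finite values as a
    land-pixel vector.
    """
    values, header = read_asc(path)
    land = np.isfinite(values)
    grid = LatticeGrid.regular(
        int(header["nrows"]), int(header["ncols"]),
        pixel_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        lat_range=lat_range, land_mask=land,
    )
    return grid, values[land]


def write_richness_asc(path, rmap: RichnessMap) -> None:
    write_asc(path, rmap.grid.to_full(rmap.richness), rmap.grid.origin,
              rmap.grid.pixel_size)


def read_richness_asc(path, lat_range: tuple[float, float] = (40.0, 52.0)
                      ) -> RichnessMap:
    grid, values = grid_from_asc(path, lat_range)
    return RichnessMap(grid, values)
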