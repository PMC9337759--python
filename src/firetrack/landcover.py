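"""Land-cover layers co-registered to the analysis grid, plus raster text I/O.

The classifier needs four static layers per cell: fractional tree cover for
the year-2000 baseline, the year of subsequent tree-cover loss (if any), a
historic-deforestation flag for the trailing five-year window, and
aboveground biomass.  A fifth layer, per-year historic detection counts, is
used only to exclude static heat sources (gas flares, industrial sites).

Rasters are exchanged as ESRI ASCII grids (plain text, row-major from the
northern edge), a format readable by any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Cell, GridSpec, OutOfExtentError

DEFAULT_HISTORIC_YEARS = (2012, 2013, 2014, 2015, 2016, 2017, 2018)


@dataclass
class LandCoverStack:
    """Co-registered land-cover layers on a :class:`GridSpec`.

    ``loss_year`` uses 0 for "no loss".  ``historic_counts`` has shape
    ``(n_years, nrows, ncols)`` with one slice per year in
    ``historic_years``.
    """

    grid: GridSpec
    tree_cover_2000: np.ndarray
    loss_year: np.ndarray
    historic_deforestation: np.ndarray
    biomass: np.ndarray
    historic_counts: np.ndarray | None = None
    historic_years: tuple[int, ...] = DEFAULT_HISTORIC_YEARS

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("tree_cover_2000", "loss_year", "historic_deforestation", "biomass"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {shape}")
        if np.nanmin(self.tree_cover_2000) < 0 or np.nanmax(self.tree_cover_2000) > 100:
            raise ValueError("tree cover outside [0, 100]%")
        if np.nanmin(self.biomass) < 0:
            raise ValueError("negative biomass")
        if self.historic_counts is not None:
            if self.historic_counts.shape != (len(self.historic_years), *shape):
                raise ValueError("historic_counts not co-registered")

    def check_cells(self, cells) -> None:
        for cell in cells:
            if not self.grid.contains_cell(cell):
                raise OutOfExtentError(f"cell {cell} outside land-cover stack")


def sample_stack(cells: set[Cell] | list[Cell], stack: LandCoverStack) -> pd.DataFrame:
    """Nearest-cell sample of every layer at the given cells.

    Returns one row per cell (index = sorted cells) with columns
    ``tree_cover_2000, loss_year, historic_deforestation, biomass``.  No
    interpolation is performed across layers.
    """
    cells = sorted(cells)
    stack.check_cells(cells)
    if not cells:
        return pd.DataFrame(
            columns=["tree_cover_2000", "loss_year", "historic_deforestation", "biomass"]
        )
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return pd.DataFrame(
        {
            "tree_cover_2000": stack.tree_cover_2000[rows, cols],
            "loss_year": stack.loss_year[rows, cols],
            "historic_deforestation": stack.historic_deforestation[rows, cols],
            "biomass": stack.biomass[rows, cols],
        },
        index=pd.Index(cells, name="cell", tupleize_cols=False),
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid text rasters


def write_ascii_grid(
    array: np.ndarray, grid: GridSpec, path: str | Path, nodata: float = -9999,
    fmt: str = "%.6f",
) -> None:
    """Write a single-band raster as an ESRI ASCII grid (WGS84 lon/lat)."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid {grid.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.extent[0]:.10g}\n"
        f"yllcorner {grid.extent[1]:.10g}\n"
        f"cellsize {grid.res:.10g}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids run north to south; row 0 of the grid is the south edge
        np.savetxt(fh, out[::-1], fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA becomes NaN."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(f"raster body {data.shape} != header ({nrows}, {ncols})")
    res = header["cellsize"]
    x0, y0 = header["xllcorner"], header["yllcorner"]
    grid = GridSpec(extent=(x0, y0, x0 + ncols * res, y0 + nrows * res), res=res)
    arr = data[::-1].copy()
    arr[arr == header["nodata_value"]] = np.nan
    return arr, grid
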