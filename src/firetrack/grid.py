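"""Analysis grid for gridding satellite active-fire detections.

The tracker works on a regular latitude/longitude grid (default 0.005°,
roughly 550 m at the equator) anchored at integer degrees so that the same
point always falls in the same cell regardless of the processing extent.
Cells are half-open rectangles [k*res, (k+1)*res) in both axes, indexed
(row, col) from the south-west corner of the extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: km per degree of latitude (spherical mean Earth radius convention).
KM_PER_DEG = 111.32

#: guard against accumulated floating point error when snapping coordinates
#: to cell boundaries; expressed as a fraction of a cell.
_EDGE_EPS = 1e-9

Cell = tuple[int, int]


class OutOfExtentError(ValueError):
    """A coordinate or cell falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with half-open cells anchored at integer degrees.

    Parameters
    ----------
    extent:
        ``(lon_min, lat_min, lon_max, lat_max)`` in decimal degrees.  Each
        edge must be an integer multiple of ``res`` away from the integer-
        degree origin ``(floor(lon_min), floor(lat_min))``.
    res:
        Cell size in decimal degrees (default 0.005).
    """

    extent: tuple[float, float, float, float]
    res: float = 0.005
    origin: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        lon_min, lat_min, lon_max, lat_max = self.extent
        if self.res <= 0:
            raise ValueError(f"resolution must be positive, got {self.res}")
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValueError(f"degenerate extent {self.extent}")
        origin = (math.floor(lon_min), math.floor(lat_min))
        object.__setattr__(self, "origin", origin)
        for edge, o in ((lon_min, origin[0]), (lon_max, origin[0]),
                        (lat_min, origin[1]), (lat_max, origin[1])):
            steps = (edge - o) / self.res
            if abs(steps - round(steps)) > 1e-6:
                raise ValueError(
                    f"extent edge {edge} is not aligned to the {self.res}° "
                    f"grid anchored at {o}"
                )

    @property
    def nrows(self) -> int:
        return round((self.extent[3] - self.extent[1]) / self.res)

    @property
    def ncols(self) -> int:
        return round((self.extent[2] - self.extent[0]) / self.res)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_index(self, lon: float, lat: float) -> Cell:
        """Return the (row, col) of the half-open cell containing a point."""
        lon_min, lat_min, lon_max, lat_max = self.extent
        if not (lon_min <= lon < lon_max and lat_min <= lat < lat_max):
            raise OutOfExtentError(
                f"point ({lon}, {lat}) outside grid extent {self.extent}"
            )
        row = int(math.floor((lat - lat_min) / self.res + _EDGE_EPS))
        col = int(math.floor((lon - lon_min) / self.res + _EDGE_EPS))
        return (min(row, self.nrows - 1), min(col, self.ncols - 1))

    def contains_cell(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.nrows and 0 <= c < self.ncols

    def cell_bounds(self, cell: Cell) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of a cell rectangle."""
        r, c = cell
        lon0 = self.extent[0] + c * self.res
        lat0 = self.extent[1] + r * self.res
        return (lon0, lat0, lon0 + self.res, lat0 + self.res)

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        x0, y0, x1, y1 = self.cell_bounds(cell)
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def cell_area_km2(self, cell: Cell) -> float:
        """Spherical-approximation area of a cell in km².

        ``(res * 111.32 km)² * cos(latitude of cell center)`` — adequate at
        tropical latitudes where the tracker is intended to run.
        """
        _, lat = self.cell_center(cell)
        return (self.res * KM_PER_DEG) ** 2 * math.cos(math.radians(lat))

    def area_km2(self, cells) -> float:
        """Summed cell area over an iterable of cells."""
        return float(sum(self.cell_area_km2(c) for c in cells))

    def row_lat_centers(self) -> np.ndarray:
        lat_min = self.extent[1]
        return lat_min + (np.arange(self.nrows) + 0.5) * self.res


#: offsets of the 8-neighborhood used for event adjacency.
NEIGHBORS_8: tuple[Cell, ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def neighbors8(cell: Cell) -> list[Cell]:
    r, c = cell
    return [(r + dr, c + dc) for dr, dc in NEIGHBORS_8]
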