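"""Shared builders for the test suite: detections, events, random scenes."""

from __future__ import annotations

import numpy as np

from firetrack.detections import CellObservation, Detection, grid_detections
from firetrack.grid import GridSpec
from firetrack.tracking import FireEvent

SMALL_GRID = GridSpec(extent=(0.0, 0.0, 0.5, 0.5), res=0.005)


def det(
    lon: float = 0.0025,
    lat: float = 0.0025,
    day: int = 200,
    time: int = 720,
    frp: float = 10.0,
    dn: str = "D",
    sat: str = "SNPP",
    conf: str = "n",
) -> Detection:
    return Detection(lon, lat, day, time, frp, dn, sat, conf)


def cell_det(grid: GridSpec, cell, day, **kw) -> Detection:
    lon, lat = grid.cell_center(cell)
    return det(lon=lon, lat=lat, day=day, **kw)


def build_event(
    grid: GridSpec,
    cells_days: dict,
    event_id: int = 0,
    frp: float = 10.0,
    dn: str = "D",
    per_day: int = 1,
) -> FireEvent:
    """Event from a {cell: [active days]} mapping, one or more detections per day."""
    obs = {}
    for cell, days in cells_days.items():
        o = CellObservation(cell)
        for d in days:
            for _ in range(per_day):
                o.add(cell_det(grid, cell, d, frp=frp, dn=dn))
        obs[cell] = o
    return FireEvent(event_id=event_id, cell_obs=obs, grid=grid)


def random_scene(
    rng: np.random.Generator,
    side: int = 30,
    n_det: int = 150,
    day_range: tuple[int, int] = (200, 240),
):
    """Random gridded detections on a side×side grid for clustering tests."""
    grid = GridSpec(extent=(0.0, 0.0, side * 0.005, side * 0.005), res=0.005)
    dets = []
    for _ in range(n_det):
        r = int(rng.integers(0, side))
        c = int(rng.integers(0, side))
        lon, lat = grid.cell_center((r, c))
        day = int(rng.integers(*day_range))
        dets.append(det(lon=lon, lat=lat, day=day, time=int(rng.integers(0, 1440))))
    return grid, grid_detections(dets, grid)


def brute_force_partition(cells: dict, window: int) -> set[frozenset]:
    """Independent clustering oracle: explicit pairwise links + networkx
    connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(cells)
    items = list(cells.items())
    for i, (ca, oa) in enumerate(items):
        for cb, ob in items[i + 1 :]:
            if max(abs(ca[0] - cb[0]), abs(ca[1] - cb[1])) != 1:
                continue
            da, db = oa.active_days, ob.active_days
            if min(abs(x - y) for x in da for y in db) <= window:
                g.add_edge(ca, cb)
    return {frozenset(comp) for comp in nx.connected_components(g)}


def partition_of(events) -> set[frozenset]:
    return {frozenset(e.footprint) for e in events}
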