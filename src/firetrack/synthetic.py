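"""Seeded generator of synthetic fire seasons with ground truth.

Every stage of the pipeline is testable offline against seasons generated
here: a block-structured tropical landscape (closed-canopy forest blocks
with ≥ 50% tree cover and moist-forest biomass, open savanna blocks below
50%), plus detection streams for five archetypes whose behavior mirrors
the patterns the classifier keys on:

* ``deforestation`` — a few cells on a historic-deforestation patch burning
  repeatedly over several days at high FRP (piled-debris combustion);
* ``forest`` — a slow contiguous understory front advancing ~200–380 m/day
  for one to three weeks at low FRP with dense detections (> 10 per km²);
* ``small`` — at most 5 detections on a single day;
* ``savanna`` — a fast narrow front sweeping kilometres per day across
  low-tree-cover blocks with a strong daytime bias;
* ``static`` — a persistent non-fire heat source: one cell recurring for
  weeks, with planted historic-year detection counts that the
  static-source filter must catch.

Events are laid out on a block lattice with spatial margins so the true
partition of detections into events is unambiguous; the reference burned-
area raster is derived from the true footprints with a per-type detection
ratio (savanna/deforestation fully mapped, small fires mostly missed,
dense-canopy forest fires omitted).  All randomness flows from a single
seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import DEFORESTATION, FOREST, SAVANNA, SMALL
from .detections import Detection, write_detections
from .grid import Cell, GridSpec
from .landcover import DEFAULT_HISTORIC_YEARS, LandCoverStack, write_ascii_grid

STATIC = "static"
ARCHETYPES = (DEFORESTATION, FOREST, SMALL, SAVANNA, STATIC)

#: mean FRP (MW) of the lognormal per-detection draw, by archetype;
#: deforestation burns hot (~15–16 MW), the other vegetation fires ~11 MW.
FRP_MEAN = {DEFORESTATION: 15.5, FOREST: 10.0, SMALL: 11.0, SAVANNA: 11.0, STATIC: 25.0}
FRP_SIGMA = 0.4
#: probability a detection is a daytime overpass, by archetype.
DAY_PROB = {DEFORESTATION: 0.55, FOREST: 0.5, SMALL: 0.7, SAVANNA: 0.85, STATIC: 0.5}

CELL_M = 550.0  # nominal cell size in meters at the study latitudes


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class SeasonSpec:
    """Study conditions of a synthetic season."""

    extent: tuple[float, float, float, float] = (-60.0, -10.0, -59.0, -9.0)
    res: float = 0.005
    n_deforestation: int = 10
    n_forest: int = 4
    n_small: int = 18
    n_savanna: int = 10
    n_static: int = 3
    season: tuple[int, int] = (182, 300)   # day-of-year range (early Jul–late Oct)
    forest_fraction: float = 0.5
    #: fraction of true footprint cells present in the reference burned-area
    #: raster, per type (dense-canopy forest fires are missed entirely).
    ba_detection_ratio: tuple[tuple[str, float], ...] = (
        (SAVANNA, 1.0), (DEFORESTATION, 1.0), (SMALL, 0.1), (FOREST, 0.0),
    )

    @property
    def counts(self) -> dict[str, int]:
        return {
            DEFORESTATION: self.n_deforestation,
            FOREST: self.n_forest,
            SMALL: self.n_small,
            SAVANNA: self.n_savanna,
            STATIC: self.n_static,
        }

    @property
    def grid(self) -> GridSpec:
        return GridSpec(extent=self.extent, res=self.res)


@dataclass
class TruthRecord:
    """Ground truth for one generated event."""

    truth_id: int
    archetype: str
    origin: Cell
    start_day: int
    cells: set[Cell]
    first_days: dict[Cell, int]
    n_detections: int


@dataclass
class SeasonData:
    spec: SeasonSpec
    grid: GridSpec
    detections: list[Detection]
    stack: LandCoverStack
    ba_raster: np.ndarray
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "truth_id": [t.truth_id for t in self.truth],
                "archetype": [t.archetype for t in self.truth],
                "ignition_row": [t.origin[0] for t in self.truth],
                "ignition_col": [t.origin[1] for t in self.truth],
                "start_day": [t.start_day for t in self.truth],
                "n_cells": [len(t.cells) for t in self.truth],
                "n_detections": [t.n_detections for t in self.truth],
            }
        )


# ---------------------------------------------------------------------------
# landscape painting


def _paint_forest(rng, tc, biomass, rows, cols) -> None:
    base_tc = rng.uniform(55.0, 95.0)
    base_bio = rng.uniform(150.0, 280.0)
    tc[rows, cols] = np.clip(
        base_tc + rng.uniform(-5, 5, size=tc[rows, cols].shape), 51.0, 100.0
    )
    biomass[rows, cols] = np.clip(
        base_bio + rng.uniform(-20, 20, size=tc[rows, cols].shape), 125.0, None
    )


def _paint_savanna(rng, tc, biomass, rows, cols) -> None:
    base_tc = rng.uniform(5.0, 45.0)
    tc[rows, cols] = np.clip(
        base_tc + rng.uniform(-4, 4, size=tc[rows, cols].shape), 0.0, 49.0
    )
    biomass[rows, cols] = rng.uniform(20.0, 80.0, size=tc[rows, cols].shape)


def _block_lattice(grid: GridSpec, n_needed: int) -> tuple[int, list[tuple[int, int]]]:
    """Square block size (cells) and block origins covering the grid."""
    max_side = min(grid.nrows, grid.ncols)
    n_side = max(2, math.ceil(math.sqrt(n_needed * 1.3)))
    block = max_side // n_side
    if block < 16:
        block = 16
        n_side = max_side // block
        if n_side * n_side < n_needed:
            raise PlacementError(
                f"extent too small for {n_needed} events "
                f"({n_side * n_side} blocks of {block} cells available)"
            )
    origins = [
        (r * block, c * block)
        for r in range(grid.nrows // block)
        for c in range(grid.ncols // block)
    ]
    return block, origins


def make_landscape(spec: SeasonSpec, seed: int) -> LandCoverStack:
    """Standalone landscape with the statistical structure the classifier assumes."""
    rng = np.random.default_rng(seed)
    grid = spec.grid
    stack = _empty_stack(grid)
    block, origins = _block_lattice(grid, max(sum(spec.counts.values()), 16))
    n_forest_blocks = round(spec.forest_fraction * len(origins))
    kinds = [FOREST] * n_forest_blocks + [SAVANNA] * (len(origins) - n_forest_blocks)
    rng.shuffle(kinds)
    for (r0, c0), kind in zip(origins, kinds):
        sl = (slice(r0, r0 + block), slice(c0, c0 + block))
        if kind == FOREST:
            _paint_forest(rng, stack.tree_cover_2000, stack.biomass, *sl)
            if rng.random() < 0.3:  # historic-deforestation patch
                pr, pc = r0 + block // 2, c0 + block // 2
                half = max(2, block // 8)
                patch = (slice(pr - half, pr + half), slice(pc - half, pc + half))
                stack.historic_deforestation[patch] = True
                stack.loss_year[patch] = rng.integers(2014, 2019)
        else:
            _paint_savanna(rng, stack.tree_cover_2000, stack.biomass, *sl)
    _plant_static_cells(rng, stack, spec.n_static)
    return stack


def _empty_stack(grid: GridSpec) -> LandCoverStack:
    shape = grid.shape
    return LandCoverStack(
        grid=grid,
        tree_cover_2000=np.full(shape, 30.0),
        loss_year=np.zeros(shape, dtype=int),
        historic_deforestation=np.zeros(shape, dtype=bool),
        biomass=np.full(shape, 50.0),
        historic_counts=np.zeros((len(DEFAULT_HISTORIC_YEARS), *shape), dtype=int),
    )


def _plant_static_cells(rng, stack: LandCoverStack, n: int) -> list[Cell]:
    """Plant historic detection counts of persistent heat sources."""
    cells = []
    for _ in range(n):
        r = int(rng.integers(2, stack.grid.nrows - 2))
        c = int(rng.integers(2, stack.grid.ncols - 2))
        n_years = int(rng.integers(3, 8))
        years = rng.choice(len(DEFAULT_HISTORIC_YEARS), size=n_years, replace=False)
        for y in years:
            stack.historic_counts[y, r, c] = int(rng.integers(25, 61))
        cells.append((r, c))
    return cells


# ---------------------------------------------------------------------------
# event simulation


def _make_detection(
    rng, grid: GridSpec, cell: Cell, day: int, archetype: str
) -> Detection:
    x0, y0, x1, y1 = grid.cell_bounds(cell)
    # keep jitter strictly inside the half-open cell
    lon = x0 + rng.uniform(0.05, 0.95) * (x1 - x0)
    lat = y0 + rng.uniform(0.05, 0.95) * (y1 - y0)
    is_day = rng.random() < DAY_PROB[archetype]
    acq_time = int(rng.integers(720, 901)) if is_day else int(rng.integers(60, 241))
    mu = math.log(FRP_MEAN[archetype]) - FRP_SIGMA**2 / 2
    return Detection(
        lon=round(lon, 6),
        lat=round(lat, 6),
        acq_day=day,
        acq_time=acq_time,
        frp=round(float(rng.lognormal(mu, FRP_SIGMA)), 2),
        daynight="D" if is_day else "N",
        satellite="SNPP" if rng.random() < 0.5 else "NOAA20",
        confidence=str(rng.choice(["n", "n", "n", "h", "l"])),
    )


def _sim_deforestation(rng, grid, origin, start_day, max_r):
    r0, c0 = origin
    k = int(rng.integers(2, 4))
    cells = [(r0, c0), (r0, c0 + 1), (r0 + 1, c0)][:k]
    duration = int(rng.integers(3, 9))
    dets, first_days = [], {}
    for cell in cells:
        days = [start_day, start_day + duration - 1]
        days += [
            start_day + d for d in range(1, duration - 1) if rng.random() < 0.75
        ]
        for day in sorted(set(days)):
            first_days.setdefault(cell, day)
            for _ in range(int(rng.integers(1, 4))):
                dets.append(_make_detection(rng, grid, cell, day, DEFORESTATION))
    return dets, first_days


def _sim_forest(rng, grid, origin, start_day, max_r):
    r0, c0 = origin
    duration = int(rng.integers(8, 19))
    rates_m = rng.uniform(180.0, 380.0, size=duration)  # m/day, within 100-400
    radius_m = np.cumsum(rates_m)
    radius_m = np.minimum(radius_m, max_r * CELL_M)
    dets, first_days = [], {}
    span = int(radius_m[-1] / CELL_M) + 1
    prev_r = 0.0
    smolder: list[Cell] = []
    for t in range(duration):
        day = start_day + t
        new_cells = []
        for dr in range(-span, span + 1):
            for dc in range(-span, span + 1):
                dist = math.hypot(dr, dc) * CELL_M
                if prev_r < dist <= radius_m[t] or (t == 0 and dist == 0.0):
                    new_cells.append((r0 + dr, c0 + dc))
        prev_r = radius_m[t]
        for cell in sorted(new_cells):
            first_days[cell] = day
            for _ in range(int(rng.integers(2, 5))):
                dets.append(_make_detection(rng, grid, cell, day, FOREST))
            if rng.random() < 0.5:
                smolder.append(cell)
        # residual smoldering: cells ignited yesterday burn into today
        for cell in [c for c in smolder if first_days[c] == day - 1]:
            for _ in range(int(rng.integers(1, 3))):
                dets.append(_make_detection(rng, grid, cell, day, FOREST))
    return dets, first_days


def _sim_small(rng, grid, origin, start_day, max_r):
    r0, c0 = origin
    n = int(rng.integers(1, 6))
    cells = [(r0, c0)] if n <= 2 else [(r0, c0), (r0, c0 + 1)]
    dets, first_days = [], {}
    for i in range(n):
        cell = cells[i % len(cells)]
        first_days.setdefault(cell, start_day)
        dets.append(_make_detection(rng, grid, cell, start_day, SMALL))
    return dets, first_days


def _sim_savanna(rng, grid, origin, start_day, max_r):
    r0, c0 = origin
    theta = rng.uniform(0, 2 * math.pi)
    ux, uy = math.cos(theta), math.sin(theta)
    speed_cells = rng.uniform(2.5, 6.0)        # ≈ 1.4–3.3 km/day
    duration = int(rng.integers(1, 5))
    half_width = rng.uniform(0.8, 1.6)
    max_along = min(speed_cells * duration, max_r - 1)
    dets, first_days = [], {}
    span = int(max_along) + 2
    for dr in range(-span, span + 1):
        for dc in range(-span, span + 1):
            along = dc * ux + dr * uy
            perp = abs(-dc * uy + dr * ux)
            if 0 <= along <= max_along and perp <= half_width:
                day = start_day + min(int(along / speed_cells), duration - 1)
                cell = (r0 + dr, c0 + dc)
                first_days[cell] = day
                for _ in range(int(rng.integers(1, 3))):
                    dets.append(_make_detection(rng, grid, cell, day, SAVANNA))
    return dets, first_days


def _sim_static(rng, grid, origin, start_day, max_r):
    dets, first_days = [], {}
    day = start_day
    end = start_day + int(rng.integers(20, 46))
    first_days[origin] = start_day
    while day <= end:
        for _ in range(int(rng.integers(1, 3))):
            dets.append(_make_detection(rng, grid, origin, day, STATIC))
        day += int(rng.integers(1, 5))
    return dets, first_days


_SIMULATORS = {
    DEFORESTATION: _sim_deforestation,
    FOREST: _sim_forest,
    SMALL: _sim_small,
    SAVANNA: _sim_savanna,
    STATIC: _sim_static,
}


def _origin_ok(archetype: str, stack: LandCoverStack, cell: Cell) -> bool:
    r, c = cell
    tc = stack.tree_cover_2000[r, c]
    if archetype == SAVANNA:
        return tc < 50.0
    if archetype == DEFORESTATION:
        return bool(stack.historic_deforestation[r, c]) and tc >= 50.0
    if archetype in (FOREST, SMALL):
        return (
            tc >= 50.0
            and stack.biomass[r, c] >= 120.0
            and not stack.historic_deforestation[r, c]
        )
    return True  # static sources sit anywhere


def simulate_event(
    archetype: str,
    landscape: LandCoverStack,
    seed: int | np.random.Generator,
    origin: Cell | None = None,
    start_day: int = 200,
    max_radius_cells: int = 12,
) -> tuple[list[Detection], TruthRecord]:
    """Simulate one event of the given archetype on a landscape.

    Without an explicit ``origin``, candidate cells are drawn at random and
    checked against the archetype's land-cover constraints (200 retries,
    then :class:`PlacementError`).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = landscape.grid
    if origin is None:
        margin = max_radius_cells + 2
        for _ in range(200):
            cand = (
                int(rng.integers(margin, grid.nrows - margin)),
                int(rng.integers(margin, grid.ncols - margin)),
            )
            if _origin_ok(archetype, landscape, cand):
                origin = cand
                break
        else:
            raise PlacementError(f"no valid origin found for {archetype!r}")
    dets, first_days = _SIMULATORS[archetype](rng, grid, origin, start_day, max_radius_cells)
    truth = TruthRecord(
        truth_id=-1,
        archetype=archetype,
        origin=origin,
        start_day=start_day,
        cells=set(first_days),
        first_days=first_days,
        n_detections=len(dets),
    )
    return dets, truth


def simulate_season(spec: SeasonSpec, seed: int) -> SeasonData:
    """Generate a full synthetic season: landscape, detections, reference
    burned area, and truth labels."""
    rng = np.random.default_rng(seed)
    grid = spec.grid
    stack = _empty_stack(grid)
    total = sum(spec.counts.values())
    block, origins = _block_lattice(grid, total)
    order = rng.permutation(len(origins))
    slots = [origins[i] for i in order]
    assignments: list[tuple[str, tuple[int, int]]] = []
    i = 0
    for archetype in ARCHETYPES:
        for _ in range(spec.counts[archetype]):
            assignments.append((archetype, slots[i]))
            i += 1
    background = slots[i:]

    # paint event blocks with the cover their archetype requires
    margin = 3
    half = block // 2
    truth: list[TruthRecord] = []
    detections: list[Detection] = []
    season_lo, season_hi = spec.season
    for truth_id, (archetype, (r0, c0)) in enumerate(assignments):
        sl = (slice(r0, r0 + block), slice(c0, c0 + block))
        center = (r0 + half, c0 + half)
        if archetype == SAVANNA:
            _paint_savanna(rng, stack.tree_cover_2000, stack.biomass, *sl)
        else:
            _paint_forest(rng, stack.tree_cover_2000, stack.biomass, *sl)
        if archetype == DEFORESTATION:
            patch = (
                slice(center[0] - 3, center[0] + 4),
                slice(center[1] - 3, center[1] + 4),
            )
            stack.historic_deforestation[patch] = True
            stack.loss_year[patch] = int(rng.integers(2014, 2019))
        if archetype == STATIC:
            n_years = int(rng.integers(3, 8))
            years = rng.choice(len(DEFAULT_HISTORIC_YEARS), size=n_years, replace=False)
            for y in sorted(years):
                stack.historic_counts[y, center[0], center[1]] = int(rng.integers(25, 61))
        start = int(rng.integers(season_lo, season_hi - 50))
        dets, rec = simulate_event(
            archetype,
            stack,
            rng,
            origin=center,
            start_day=start,
            max_radius_cells=half - margin,
        )
        rec.truth_id = truth_id
        truth.append(rec)
        detections.extend(dets)

    # background cover to approach the requested forest fraction
    n_forest_assigned = sum(
        1 for a, _ in assignments if a != SAVANNA
    )
    want_forest = round(spec.forest_fraction * len(origins))
    n_bg_forest = int(np.clip(want_forest - n_forest_assigned, 0, len(background)))
    for j, (r0, c0) in enumerate(background):
        sl = (slice(r0, r0 + block), slice(c0, c0 + block))
        if j < n_bg_forest:
            _paint_forest(rng, stack.tree_cover_2000, stack.biomass, *sl)
        else:
            _paint_savanna(rng, stack.tree_cover_2000, stack.biomass, *sl)

    # reference burned-area raster from true footprints
    ratios = dict(spec.ba_detection_ratio)
    ba = np.zeros(grid.shape)
    for rec in truth:
        ratio = ratios.get(rec.archetype, 0.0)
        for cell in sorted(rec.cells):
            if rng.random() < ratio:
                ba[cell] = rec.first_days[cell]

    order = rng.permutation(len(detections))
    detections = [detections[k] for k in order]
    return SeasonData(
        spec=spec, grid=grid, detections=detections, stack=stack,
        ba_raster=ba, truth=truth,
    )


def write_season(season: SeasonData, outdir: str | Path) -> None:
    """Write a season to text files (detection CSV, ASCII-grid rasters, truth CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = season.grid
    write_detections(season.detections, outdir / "detections.csv")
    stack = season.stack
    write_ascii_grid(stack.tree_cover_2000, grid, outdir / "tree_cover_2000.asc")
    write_ascii_grid(stack.loss_year, grid, outdir / "loss_year.asc", fmt="%d")
    write_ascii_grid(
        stack.historic_deforestation.astype(float), grid,
        outdir / "historic_deforestation.asc", fmt="%d",
    )
    write_ascii_grid(stack.biomass, grid, outdir / "biomass.asc")
    if stack.historic_counts is not None:
        for i, year in enumerate(stack.historic_years):
            write_ascii_grid(
                stack.historic_counts[i].astype(float), grid,
                outdir / f"historic_counts_{year}.asc", fmt="%d",
            )
    write_ascii_grid(season.ba_raster, grid, outdir / "ba_ref.asc", fmt="%d")
    season.truth_frame().to_csv(outdir / "truth.csv", index=False)
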