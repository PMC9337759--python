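"""Clustering of gridded detections into individual fire events.

Cells are linked into one fire when they are 8-adjacent and active within a
short temporal window of each other: a fire may spread into a neighboring
~550-m cell up to ``window`` days (default 5) after the last detection in a
cell.  Formally, two adjacent cells link iff some detection day of one lies
within ``window`` days of some detection day of the other.  This predicate
is symmetric and order-independent, so batch clustering of a whole season
(:func:`cluster_season`) and day-by-day incremental tracking
(:class:`Tracker`) produce identical partitions — the property that makes
the near-real-time mode trustworthy.

Ignition location is estimated after smoothing per-cell burn dates with a
3×3 median filter restricted to the event footprint, which suppresses
single-cell date outliers from residual geolocation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detections import CellObservation, Detection
from .grid import Cell, GridSpec, NEIGHBORS_8, neighbors8

DEFAULT_WINDOW = 5

# static-source exclusion defaults: a cell with more than this many
# detections in at least `STATIC_MIN_YEARS` of the historic years marks the
# whole event as a persistent non-fire heat source.
STATIC_DETECTIONS_PER_YEAR = 20
STATIC_MIN_YEARS = 3


class SequencingError(RuntimeError):
    """Days fed to the incremental tracker must strictly increase."""


def cells_linked(a: CellObservation, b: CellObservation, window: int) -> bool:
    """True iff some active day of ``a`` is within ``window`` days of one of ``b``.

    Both day lists are sorted; a two-pointer sweep finds the minimum gap.
    """
    da, db = a.active_days, b.active_days
    i = j = 0
    while i < len(da) and j < len(db):
        gap = da[i] - db[j]
        if abs(gap) <= window:
            return True
        if gap < 0:
            i += 1
        else:
            j += 1
    return False


@dataclass(eq=False)
class FireEvent:
    """A spatiotemporally connected cluster of detection cells.

    Equality and hashing are by identity: two event objects are distinct
    even if they currently hold the same cells.
    """

    event_id: int
    cell_obs: dict[Cell, CellObservation]
    grid: GridSpec
    fire_type: str | None = None      # final classification, set by the pipeline
    confidence: str | None = None
    burned_area_km2: float | None = None
    emissions: tuple[float, float] | None = None   # (dry matter Gg, carbon Gg)
    _ignition: tuple[Cell, int] | None = field(default=None, repr=False)

    @property
    def footprint(self) -> set[Cell]:
        return set(self.cell_obs)

    @property
    def start_day(self) -> int:
        return min(o.first_day for o in self.cell_obs.values())

    @property
    def end_day(self) -> int:
        return max(o.last_day for o in self.cell_obs.values())

    @property
    def duration(self) -> int:
        return self.end_day - self.start_day + 1

    @property
    def n_detections(self) -> int:
        return sum(o.n_detections for o in self.cell_obs.values())

    @property
    def detections(self) -> list[Detection]:
        return [d for c in sorted(self.cell_obs) for d in self.cell_obs[c].detections]

    @property
    def daily_history(self) -> dict[int, set[Cell]]:
        """Day -> cells newly active (first detection) that day."""
        hist: dict[int, set[Cell]] = {}
        for cell, obs in self.cell_obs.items():
            hist.setdefault(obs.first_day, set()).add(cell)
        return {d: hist[d] for d in sorted(hist)}

    @property
    def active_days(self) -> list[int]:
        return sorted({day for o in self.cell_obs.values() for day in o.active_days})

    @property
    def ignition(self) -> tuple[Cell, int]:
        if self._ignition is None:
            self._ignition = estimate_ignition(self)
        return self._ignition

    @property
    def ignition_cell(self) -> Cell:
        return self.ignition[0]

    @property
    def ignition_day(self) -> int:
        return self.ignition[1]

    @property
    def ignition_lonlat(self) -> tuple[float, float]:
        return self.grid.cell_center(self.ignition_cell)

    @property
    def size_km2(self) -> float:
        return self.grid.area_km2(self.cell_obs)

    def is_connected(self) -> bool:
        """Flood-fill check that the footprint is 8-connected."""
        cells = self.footprint
        if not cells:
            return False
        seen = {next(iter(cells))}
        stack = list(seen)
        while stack:
            cur = stack.pop()
            for nb in neighbors8(cur):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == cells


def cluster_season(
    cells: dict[Cell, CellObservation],
    window: int = DEFAULT_WINDOW,
    grid: GridSpec | None = None,
) -> list[FireEvent]:
    """Partition gridded detections into fire events (batch mode).

    Union-find over the within-window adjacency links.  Events are numbered
    by ignition order (start day, then cell) for reproducibility.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    parent: dict[Cell, Cell] = {c: c for c in cells}

    def find(c: Cell) -> Cell:
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    def union(a: Cell, b: Cell) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for cell in cells:
        r, c = cell
        # forward half of the 8-neighborhood: each pair checked once
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (r + dr, c + dc)
            if nb in cells and cells_linked(cells[cell], cells[nb], window):
                union(cell, nb)

    groups: dict[Cell, dict[Cell, CellObservation]] = {}
    for cell in cells:
        groups.setdefault(find(cell), {})[cell] = cells[cell]
    ordered = sorted(
        groups.values(),
        key=lambda g: (min(o.first_day for o in g.values()), min(g)),
    )
    return [
        FireEvent(event_id=i, cell_obs=dict(sorted(g.items())), grid=grid)
        for i, g in enumerate(ordered)
    ]


def smooth_burn_dates(event: FireEvent) -> dict[Cell, int]:
    """3×3 footprint-restricted median filter of per-cell burn dates.

    Even neighbor counts take the lower median.  The result feeds ignition
    estimation only; the raw per-cell observations are never mutated.
    """
    first = {c: o.first_day for c, o in event.cell_obs.items()}
    out: dict[Cell, int] = {}
    for cell in first:
        days = [first[cell]]
        days += [first[nb] for nb in neighbors8(cell) if nb in first]
        days.sort()
        out[cell] = days[(len(days) - 1) // 2]
    return out


def estimate_ignition(event: FireEvent) -> tuple[Cell, int]:
    """Ignition cell and day from the smoothed burn-date field.

    The ignition cell minimizes the filtered burn date; ties break on the
    earliest raw detection timestamp, then on (row, col).  The ignition day
    is the chosen cell's raw first detection day.
    """
    filtered = smooth_burn_dates(event)
    cell = min(
        event.cell_obs,
        key=lambda c: (filtered[c], event.cell_obs[c].earliest.timestamp, c),
    )
    return cell, event.cell_obs[cell].first_day


def filter_static_sources(
    events: list[FireEvent],
    historic_counts,
    per_year: int = STATIC_DETECTIONS_PER_YEAR,
    min_years: int = STATIC_MIN_YEARS,
) -> tuple[list[FireEvent], list[tuple[FireEvent, list[Cell]]]]:
    """Split events into (kept, removed) by the static-source rule.

    An event is removed iff any of its cells has more than ``per_year``
    detections in at least ``min_years`` of the historic years.  Removed
    events are returned with their triggering cells.

    ``historic_counts`` is the ``(n_years, nrows, ncols)`` array from
    :class:`~firetrack.landcover.LandCoverStack`.
    """
    if historic_counts is None:
        raise ValueError("historic detection counts layer is required")
    kept: list[FireEvent] = []
    removed: list[tuple[FireEvent, list[Cell]]] = []
    for ev in events:
        triggers = [
            cell
            for cell in sorted(ev.cell_obs)
            if int((historic_counts[:, cell[0], cell[1]] > per_year).sum()) >= min_years
        ]
        if triggers:
            removed.append((ev, triggers))
        else:
            kept.append(ev)
    return kept, removed


# ---------------------------------------------------------------------------
# Incremental (near-real-time) tracking


class Tracker:
    """Day-by-day incremental fire tracker.

    Feed one day at a time with :meth:`advance_day`; days must strictly
    increase.  At any point :attr:`open_events` are the fires that may still
    grow (last activity within the linking window) and
    :attr:`closed_events` those beyond it.  Replaying a season through the
    tracker yields exactly the :func:`cluster_season` partition.

    A closed event is re-opened if one of its own cells re-ignites — the
    open/closed distinction is a function of the current state, not a
    ratchet.
    """

    def __init__(self, window: int = DEFAULT_WINDOW, grid: GridSpec | None = None):
        if window < 0:
            raise ValueError("window must be >= 0")
        self.window = window
        self.grid = grid
        self.current_day: int | None = None
        self._obs: dict[Cell, CellObservation] = {}
        self._parent: dict[Cell, Cell] = {}
        self._event_id: dict[Cell, int] = {}       # root cell -> event id
        self._next_id = 0

    # union-find ------------------------------------------------------------
    def _find(self, c: Cell) -> Cell:
        root = c
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[c] != root:
            self._parent[c], c = root, self._parent[c]
        return root

    def _union(self, a: Cell, b: Cell) -> None:
        ra, rb = self._find(a), self._find(b)
        if ra == rb:
            return
        # merged event keeps the smaller event id
        ida, idb = self._event_id[ra], self._event_id[rb]
        if idb < ida:
            ra, rb = rb, ra
            ida, idb = idb, ida
        self._parent[rb] = ra
        del self._event_id[rb]

    # ------------------------------------------------------------------------
    def advance_day(self, day: int, day_dets: dict[Cell, list[Detection]]) -> None:
        """Ingest all detections of one day, keyed by grid cell."""
        if self.current_day is not None and day <= self.current_day:
            raise SequencingError(
                f"day {day} does not advance past {self.current_day}"
            )
        self.current_day = day
        touched: list[Cell] = []
        for cell in sorted(day_dets):
            dets = day_dets[cell]
            if not dets:
                continue
            if any(d.acq_day != day for d in dets):
                raise SequencingError(f"detection day mismatch in cell {cell}")
            obs = self._obs.get(cell)
            if obs is None:
                obs = self._obs[cell] = CellObservation(cell)
                self._parent[cell] = cell
                self._event_id[cell] = self._next_id
                self._next_id += 1
            for d in dets:
                obs.add(d)
            touched.append(cell)
        cutoff = day - self.window
        for cell in touched:
            for nb in neighbors8(cell):
                obs = self._obs.get(nb)
                if obs is not None and obs.last_day >= cutoff:
                    self._union(cell, nb)

    # ------------------------------------------------------------------------
    def _components(self) -> dict[Cell, dict[Cell, CellObservation]]:
        comps: dict[Cell, dict[Cell, CellObservation]] = {}
        for cell in self._obs:
            comps.setdefault(self._find(cell), {})[cell] = self._obs[cell]
        return comps

    def events(self) -> list[FireEvent]:
        """All events so far, open and closed, ordered by event id."""
        evs = [
            FireEvent(
                event_id=self._event_id[root],
                cell_obs=dict(sorted(comp.items())),
                grid=self.grid,
            )
            for root, comp in self._components().items()
        ]
        return sorted(evs, key=lambda e: e.event_id)

    def _is_open(self, ev: FireEvent) -> bool:
        assert self.current_day is not None
        return self.current_day - ev.end_day <= self.window

    @property
    def open_events(self) -> list[FireEvent]:
        return [e for e in self.events() if self._is_open(e)]

    @property
    def closed_events(self) -> list[FireEvent]:
        return [e for e in self.events() if not self._is_open(e)]


def replay_season(
    cells: dict[Cell, CellObservation],
    window: int = DEFAULT_WINDOW,
    grid: GridSpec | None = None,
) -> list[FireEvent]:
    """Run the incremental tracker over a gridded season, day by day."""
    by_day: dict[int, dict[Cell, list[Detection]]] = {}
    for cell, obs in cells.items():
        for det in obs.detections:
            by_day.setdefault(det.acq_day, {}).setdefault(cell, []).append(det)
    tracker = Tracker(window=window, grid=grid)
    for day in sorted(by_day):
        tracker.advance_day(day, by_day[day])
    return tracker.events()
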