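"""Per-cell and per-event fire-behavior and land-cover metrics.

Everything the fire-type classifier consumes is computed here, with an
optional cumulative cutoff day (``upto_day``) so the same code serves both
the end-of-season product and the daily near-real-time view: at cutoff
``d``, only detections acquired on or before ``d`` (and cells first active
by ``d``) contribute.

Conventions (each isolated here so a different reading is a one-line
change):

* fire persistence of a cell = number of *distinct* days with detections;
* event mean FRP = unweighted mean over detections, excluding zero-FRP
  retrievals (missing-retrieval zeros would bias intensity downward);
* event mean persistence = unweighted mean over cells;
* duration is inclusive of both end days;
* the 2014 tree-cover layer zeroes any cell with recorded loss in
  2000–2013 (full-cell loss at the ~550-m scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detections import CellObservation
from .landcover import LandCoverStack, sample_stack
from .tracking import FireEvent


class EmptyWindowError(ValueError):
    """Cutoff day precedes the event's first detection."""


@dataclass(frozen=True)
class FireBehaviorMetrics:
    n_detections: int
    mean_frp: float          # MW, over nonzero-FRP detections
    day_fraction: float      # fraction of detections flagged daytime
    mean_persistence: float  # mean distinct active days per cell
    duration: int            # days, inclusive
    size_km2: float          # footprint area
    detection_density: float  # detections per km2


@dataclass(frozen=True)
class LandCoverSummary:
    mean_tree_cover_2014: float        # %
    historic_deforestation_fraction: float
    mean_biomass: float                # t/ha


def cell_persistence(obs: CellObservation) -> int:
    """Distinct days with at least one detection in the cell."""
    return obs.persistence


def event_metrics(event: FireEvent, upto_day: int | None = None) -> FireBehaviorMetrics:
    """Cumulative fire-behavior metrics of an event up to ``upto_day``.

    With ``upto_day=None`` the full event is summarized.  Raises
    :class:`EmptyWindowError` if no detection falls on or before the cutoff.
    """
    if upto_day is None:
        upto_day = event.end_day
    if upto_day < event.start_day:
        raise EmptyWindowError(
            f"cutoff day {upto_day} precedes event start {event.start_day}"
        )
    cells = {
        c: o for c, o in event.cell_obs.items() if o.first_day <= upto_day
    }
    dets = [
        d for o in cells.values() for d in o.detections if d.acq_day <= upto_day
    ]
    n = len(dets)
    frp = [d.frp for d in dets if d.frp > 0]
    mean_frp = float(np.mean(frp)) if frp else 0.0
    day_fraction = sum(1 for d in dets if d.daynight == "D") / n
    persistence = float(
        np.mean([len({d for d in o.active_days if d <= upto_day}) for o in cells.values()])
    )
    end = min(event.end_day, upto_day)
    size = event.grid.area_km2(cells)
    return FireBehaviorMetrics(
        n_detections=n,
        mean_frp=mean_frp,
        day_fraction=day_fraction,
        mean_persistence=persistence,
        duration=end - event.start_day + 1,
        size_km2=size,
        detection_density=n / size,
    )


def tree_cover_2014(tc2000: np.ndarray, loss_year: np.ndarray) -> np.ndarray:
    """Fractional tree cover circa 2014 from the 2000 baseline and loss years.

    A cell with tree-cover loss recorded in 2000–2013 drops to 0%; losses
    after 2013 do not affect the 2014 layer.  Values clipped to [0, 100].
    """
    lost = (loss_year >= 2000) & (loss_year <= 2013)
    return np.clip(np.where(lost, 0.0, tc2000), 0.0, 100.0)


def landcover_summary(
    event: FireEvent, stack: LandCoverStack, upto_day: int | None = None
) -> LandCoverSummary:
    """Footprint-mean land-cover summary over cells active by ``upto_day``."""
    if upto_day is None:
        upto_day = event.end_day
    cells = [c for c, o in event.cell_obs.items() if o.first_day <= upto_day]
    if not cells:
        raise EmptyWindowError(f"no cells active by day {upto_day}")
    rec = sample_stack(cells, stack)
    tc2014 = tree_cover_2014(
        rec["tree_cover_2000"].to_numpy(dtype=float),
        rec["loss_year"].to_numpy(),
    )
    return LandCoverSummary(
        mean_tree_cover_2014=float(tc2014.mean()),
        historic_deforestation_fraction=float(
            rec["historic_deforestation"].to_numpy(dtype=bool).mean()
        ),
        mean_biomass=float(rec["biomass"].to_numpy(dtype=float).mean()),
    )
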