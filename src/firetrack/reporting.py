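"""Regional summaries, share statistics, and daily time series by fire type.

The packaged :data:`AMAZON_2019` table carries the published 2019 southern-
Amazon season summary by fire type (detections, mean FRP, events, mean
event size, burned area, carbon emissions) and serves as the worked example
for the share arithmetic: deforestation fires accounted for 39% of
detections and 63% of carbon emissions, small clearing/agricultural fires
for 8% of burned area, savanna and grassland fires for 55%, and the mean
forest fire was about eight times the size of the mean deforestation fire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DEFORESTATION, FIRE_TYPES, FOREST, SAVANNA, SMALL
from .grid import GridSpec
from .tracking import FireEvent

#: published 2019 fire-season summary for the southern Amazon biome.
#: units: detections and events in thousands, FRP in MW, mean size in km²,
#: burned area in thousands of km², emissions in Tg C.
AMAZON_2019 = pd.DataFrame(
    {
        "region": ["Amazon"] * 4,
        "fire_type": [DEFORESTATION, FOREST, SMALL, SAVANNA],
        "detections_k": [547.06, 163.10, 247.83, 456.21],
        "mean_frp_mw": [16.10, 10.61, 11.14, 11.04],
        "events_k": [19.71, 3.04, 113.03, 76.77],
        "mean_size_km2": [0.64, 4.98, 0.05, 0.52],
        "burned_area_kkm2": [12.52, 15.13, 5.59, 39.82],
        "emissions_tg_c": [68.90, 19.01, 7.64, 14.50],
    }
)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def largest_remainder(shares: dict[str, float], total: int = 100) -> dict[str, int]:
    """Integer percentages that sum exactly to ``total``.

    Standard largest-remainder apportionment: floor everything, then hand
    the remaining points to the largest fractional parts (ties broken by
    key for determinism).
    """
    floors = {k: math.floor(v) for k, v in shares.items()}
    remainder = total - sum(floors.values())
    order = sorted(shares, key=lambda k: (-(shares[k] - floors[k]), k))
    for k in order[:remainder]:
        floors[k] += 1
    return floors


class UndefinedShareError(ZeroDivisionError):
    pass


def share_stats(summary: pd.DataFrame, region: str) -> dict:
    """Per-type share statistics for one region of a summary table.

    Returns raw (unrounded) percentage shares of detections, burned area
    and emissions per fire type, plus detections-per-event and the
    forest/deforestation mean-size ratio.  Composition shares are also
    returned largest-remainder-rounded to integers summing to 100;
    standalone quantities should be rounded half away from zero.
    """
    rows = summary[summary["region"] == region]
    missing = set(FIRE_TYPES) - set(rows["fire_type"])
    if missing:
        raise ValueError(f"region {region!r} is missing fire types {sorted(missing)}")
    rows = rows.set_index("fire_type")
    out: dict = {"region": region}
    for quantity, col in [
        ("detections", "detections_k"),
        ("burned_area", "burned_area_kkm2"),
        ("emissions", "emissions_tg_c"),
    ]:
        total = rows[col].sum()
        if total == 0:
            raise UndefinedShareError(f"zero total {quantity} in region {region!r}")
        shares = {t: 100.0 * rows.loc[t, col] / total for t in FIRE_TYPES}
        out[f"{quantity}_share_pct"] = shares
        out[f"{quantity}_share_pct_rounded"] = largest_remainder(shares)
    out["detections_per_event"] = {
        t: (
            rows.loc[t, "detections_k"] / rows.loc[t, "events_k"]
            if rows.loc[t, "events_k"] > 0
            else math.nan
        )
        for t in FIRE_TYPES
    }
    out["forest_to_deforestation_size_ratio"] = (
        rows.loc[FOREST, "mean_size_km2"] / rows.loc[DEFORESTATION, "mean_size_km2"]
    )
    return out


# ---------------------------------------------------------------------------
# aggregation of tracked events


def regional_summary(
    events: list[FireEvent], regions: dict[str, object] | None = None
) -> pd.DataFrame:
    """Aggregate finalized events into a per-(region, type) summary table.

    ``regions`` maps names to shapely polygons; an event belongs to the
    region containing its ignition point, or to ``"unassigned"``.  With no
    regions, everything lands in a single ``"all"`` region.  Mean event
    size is total burned area over event count.
    """
    from shapely.geometry import Point

    def region_of(ev: FireEvent) -> str:
        if regions is None:
            return "all"
        pt = Point(*ev.ignition_lonlat)
        for name in sorted(regions):
            if regions[name].contains(pt):
                return name
        return "unassigned"

    rows = []
    groups: dict[tuple[str, str], list[FireEvent]] = {}
    for ev in events:
        if ev.fire_type is None:
            raise ValueError(f"event {ev.event_id} not finalized")
        groups.setdefault((region_of(ev), ev.fire_type), []).append(ev)
    for (region, fire_type) in sorted(groups):
        evs = groups[(region, fire_type)]
        frp = [d.frp for ev in evs for d in ev.detections if d.frp > 0]
        n_det = sum(ev.n_detections for ev in evs)
        ba = sum(ev.burned_area_km2 or 0.0 for ev in evs)
        emis_gg = sum(ev.emissions[1] if ev.emissions else 0.0 for ev in evs)
        rows.append(
            {
                "region": region,
                "fire_type": fire_type,
                "detections_k": n_det / 1000.0,
                "mean_frp_mw": float(np.mean(frp)) if frp else 0.0,
                "events_k": len(evs) / 1000.0,
                "mean_size_km2": ba / len(evs),
                "burned_area_kkm2": ba / 1000.0,
                "emissions_tg_c": emis_gg / 1000.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "fire_type", "detections_k", "mean_frp_mw", "events_k",
            "mean_size_km2", "burned_area_kkm2", "emissions_tg_c",
        ],
    )


AGE_CLASSES = ("new", "1-10 days", ">10 days")


def daily_series(
    events: list[FireEvent],
    precip: np.ndarray | None = None,
    precip_grid: GridSpec | None = None,
    precip_day0: int = 1,
    min_detections: int = 50,
) -> pd.DataFrame:
    """Per-day, per-type detection counts split by event age.

    Age on day ``d`` is ``d - start_day``: 0 is a new start, 1–10 an
    established multiday fire, > 10 a long-duration fire.  With a daily
    precipitation cube (days × rows × cols on a coarse grid), the mean
    precipitation over coarse cells receiving at least ``min_detections``
    season-total detections is added as a ``precip_mm`` column.
    """
    counts: dict[tuple[int, str, str], int] = {}
    for ev in events:
        if ev.fire_type is None:
            raise ValueError(f"event {ev.event_id} not finalized")
        for det in ev.detections:
            age = det.acq_day - ev.start_day
            cls = AGE_CLASSES[0] if age == 0 else AGE_CLASSES[1] if age <= 10 else AGE_CLASSES[2]
            key = (det.acq_day, ev.fire_type, cls)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"day": d, "fire_type": t, "age_class": c, "n_detections": n}
        for (d, t, c), n in sorted(counts.items())
    ]
    out = pd.DataFrame(rows, columns=["day", "fire_type", "age_class", "n_detections"])
    if precip is not None:
        if precip_grid is None:
            raise ValueError("precip_grid required with a precipitation cube")
        if precip.ndim != 3 or precip.shape[1:] != precip_grid.shape:
            raise ValueError(
                f"precipitation cube {precip.shape} does not match grid "
                f"{precip_grid.shape}"
            )
        cell_counts: dict[tuple[int, int], int] = {}
        for ev in events:
            for det in ev.detections:
                try:
                    cell = precip_grid.cell_index(det.lon, det.lat)
                except Exception:
                    continue
                cell_counts[cell] = cell_counts.get(cell, 0) + 1
        active = [c for c, n in cell_counts.items() if n >= min_detections]
        overlay = {}
        for i in range(precip.shape[0]):
            day = precip_day0 + i
            overlay[day] = (
                float(np.mean([precip[i, r, c] for r, c in active]))
                if active
                else np.nan
            )
        out["precip_mm"] = out["day"].map(overlay)
    return out
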