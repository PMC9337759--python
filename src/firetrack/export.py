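"""Export of fire-event products: GeoJSON perimeters and CSV attribute tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .landcover import LandCoverStack
from .metrics import event_metrics, landcover_summary
from .tracking import FireEvent

TABLE_COLUMNS = [
    "event_id", "ign_lon", "ign_lat", "start_day", "duration_d", "n_det",
    "frp_mw_mean", "day_frac", "persistence", "size_km2", "det_per_km2",
    "tc2014_pct", "hist_defor_frac", "agb_t_ha", "fire_type", "confidence",
    "burned_area_km2", "dry_matter_gg", "carbon_gg",
]


def event_perimeter(event: FireEvent):
    """Union of the footprint cell rectangles (WGS84 polygon)."""
    return unary_union([box(*event.grid.cell_bounds(c)) for c in sorted(event.cell_obs)])


def event_table(
    events: list[FireEvent], stack: LandCoverStack | None = None
) -> pd.DataFrame:
    rows = []
    for ev in events:
        m = event_metrics(ev)
        lon, lat = ev.ignition_lonlat
        lc = landcover_summary(ev, stack) if stack is not None else None
        dm, carbon = ev.emissions if ev.emissions is not None else (None, None)
        rows.append(
            {
                "event_id": ev.event_id,
                "ign_lon": round(lon, 6),
                "ign_lat": round(lat, 6),
                "start_day": ev.start_day,
                "duration_d": m.duration,
                "n_det": m.n_detections,
                "frp_mw_mean": round(m.mean_frp, 6),
                "day_frac": round(m.day_fraction, 6),
                "persistence": round(m.mean_persistence, 6),
                "size_km2": round(m.size_km2, 6),
                "det_per_km2": round(m.detection_density, 6),
                "tc2014_pct": round(lc.mean_tree_cover_2014, 6) if lc else None,
                "hist_defor_frac": round(lc.historic_deforestation_fraction, 6) if lc else None,
                "agb_t_ha": round(lc.mean_biomass, 6) if lc else None,
                "fire_type": ev.fire_type,
                "confidence": ev.confidence,
                "burned_area_km2": (
                    round(ev.burned_area_km2, 6) if ev.burned_area_km2 is not None else None
                ),
                "dry_matter_gg": round(dm, 6) if dm is not None else None,
                "carbon_gg": round(carbon, 6) if carbon is not None else None,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def export_events(
    events: list[FireEvent],
    perimeter_path: str | Path,
    table_path: str | Path,
    stack: LandCoverStack | None = None,
) -> None:
    """Write perimeters (GeoJSON FeatureCollection) and the attribute table (CSV)."""
    features = []
    for ev in events:
        lon, lat = ev.ignition_lonlat
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(event_perimeter(ev)),
                "properties": {
                    "event_id": ev.event_id,
                    "fire_type": ev.fire_type,
                    "confidence": ev.confidence,
                    "start_day": ev.start_day,
                    "duration_d": ev.duration,
                    "ign_lon": round(lon, 6),
                    "ign_lat": round(lat, 6),
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(perimeter_path, "w") as fh:
        json.dump(collection, fh)
        fh.write("\n")
    event_table(events, stack).to_csv(table_path, index=False, float_format="%.6f")


def read_perimeters(path: str | Path) -> list:
    """Read exported perimeters back as shapely geometries (round-trip aid)."""
    collection = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in collection["features"]]
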