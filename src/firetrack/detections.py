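"""Active-fire detection records and per-cell aggregation.

Detections mirror the 375-m VIIRS active-fire CSV dialect: one row per
thermal-anomaly pixel with center coordinates, acquisition date/time, fire
radiative power (FRP, MW), a day/night flag, satellite identifier and a
confidence class.  All confidence classes are retained.  Gridding keeps
every detection (for FRP and diurnal metrics) while the temporally earliest
detection in a cell defines the cell's burn date.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .grid import Cell, GridSpec

logger = logging.getLogger(__name__)

#: CSV columns of the detection interchange format.
CSV_COLUMNS = [
    "longitude", "latitude", "acq_date", "acq_time",
    "frp_mw", "daynight", "satellite", "confidence",
]


class FormatError(ValueError):
    """A detection file does not conform to the expected schema."""


@dataclass(frozen=True, order=True)
class Detection:
    """One satellite fire pixel."""

    lon: float
    lat: float
    acq_day: int        # UTC day of year
    acq_time: int       # minutes since midnight UTC
    frp: float          # MW, >= 0
    daynight: str       # 'D' or 'N'
    satellite: str
    confidence: str     # 'l' / 'n' / 'h'

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")
        if self.frp < 0:
            raise ValueError(f"negative FRP {self.frp}")

    @property
    def timestamp(self) -> tuple[int, int, str]:
        """Sort key for 'earliest detection': day, then time, then satellite."""
        return (self.acq_day, self.acq_time, self.satellite)


@dataclass
class CellObservation:
    """All detections that fell in one grid cell, with burn-date summary."""

    cell: Cell
    detections: list[Detection] = field(default_factory=list)

    def add(self, det: Detection) -> None:
        self.detections.append(det)

    @property
    def active_days(self) -> list[int]:
        """Sorted distinct days with at least one detection."""
        return sorted({d.acq_day for d in self.detections})

    @property
    def first_day(self) -> int:
        return min(d.acq_day for d in self.detections)

    @property
    def last_day(self) -> int:
        return max(d.acq_day for d in self.detections)

    @property
    def persistence(self) -> int:
        """Distinct active days — repeated in-place burning indicator."""
        return len({d.acq_day for d in self.detections})

    @property
    def earliest(self) -> Detection:
        """Earliest detection (day, then time, then satellite id)."""
        return min(self.detections, key=lambda d: d.timestamp)

    @property
    def n_detections(self) -> int:
        return len(self.detections)


def grid_detections(
    dets: list[Detection], grid: GridSpec
) -> dict[Cell, CellObservation]:
    """Aggregate detections onto grid cells.

    Every detection lands in exactly one :class:`CellObservation`; the
    earliest detection per cell (day, then acquisition time, then satellite
    id) defines the cell burn date, while all detections are retained.
    """
    out: dict[Cell, CellObservation] = {}
    for det in dets:
        cell = grid.cell_index(det.lon, det.lat)
        obs = out.get(cell)
        if obs is None:
            obs = out[cell] = CellObservation(cell)
        obs.add(det)
    return out


def _parse_acq_day(date_str: str) -> int:
    d = _dt.date.fromisoformat(date_str)
    return d.timetuple().tm_yday


def _parse_acq_time(time_str: str) -> int:
    s = str(time_str).strip().zfill(4)
    hh, mm = int(s[:-2] or 0), int(s[-2:])
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"bad acquisition time {time_str!r}")
    return hh * 60 + mm


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detection CSV; malformed rows are dropped with a warning.

    Raises :class:`FormatError` naming the column if a mandatory column is
    missing entirely.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    out: list[Detection] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                Detection(
                    lon=float(row.longitude),
                    lat=float(row.latitude),
                    acq_day=_parse_acq_day(row.acq_date),
                    acq_time=_parse_acq_time(row.acq_time),
                    frp=float(row.frp_mw),
                    daynight=str(row.daynight).strip().upper(),
                    satellite=str(row.satellite).strip(),
                    confidence=str(row.confidence).strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejected detection row %d of %s: %s", i, path, exc)
    return out


def _day_to_date(day: int, year: int = 2019) -> str:
    return (_dt.date(year, 1, 1) + _dt.timedelta(days=day - 1)).isoformat()


def detections_frame(dets: list[Detection], year: int = 2019) -> pd.DataFrame:
    """Detections as a DataFrame in the CSV interchange schema."""
    return pd.DataFrame(
        {
            "longitude": [round(d.lon, 6) for d in dets],
            "latitude": [round(d.lat, 6) for d in dets],
            "acq_date": [_day_to_date(d.acq_day, year) for d in dets],
            "acq_time": [f"{d.acq_time // 60:02d}{d.acq_time % 60:02d}" for d in dets],
            "frp_mw": [round(d.frp, 6) for d in dets],
            "daynight": [d.daynight for d in dets],
            "satellite": [d.satellite for d in dets],
            "confidence": [d.confidence for d in dets],
        },
        columns=CSV_COLUMNS,
    )


def write_detections(dets: list[Detection], path: str | Path, year: int = 2019) -> None:
    """Write detections in the same CSV dialect that :func:`read_detections` reads."""
    detections_frame(dets, year=year).to_csv(path, index=False, float_format="%.6f")
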