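"""Fuel consumption and carbon emissions per fire event.

Satellite fire radiative power (FRP) is an instantaneous measure; its
cumulative total per area burned correlates with — but does not equal —
fuel consumption.  The conversion is therefore calibrated empirically, per
fire type, by matching the *distribution* of event FRP densities (MW/ha)
against field-observed fuel consumption (t/ha) on a quantile-quantile plot
in log10 space and fitting a line:

    log10(FC) = intercept + slope * log10(FRP density)

Fitting uses the 2nd–98th percentile band of FRP density to discard
occasional extremes; the back-transformed predictions at the band edges cap
the model (fc_min/fc_max).  When only a single field observation exists
(forest fires), the density distribution is translated by matching means
instead, with more conservative 10th/90th percentile caps.

Carbon is dry matter times a per-type emission factor (g C per kg dry
matter): 491 for deforestation and forest fires, 480 for small
clearing/agricultural fires, 488 for savanna and grassland fires.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .classify import DEFORESTATION, FOREST, SAVANNA, SMALL
from .tracking import FireEvent

logger = logging.getLogger(__name__)

HA_PER_KM2 = 100.0


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class EmissionFactors:
    """g C emitted per kg dry matter combusted, by fire type."""

    deforestation: float = 491.0
    forest: float = 491.0
    small: float = 480.0
    savanna: float = 488.0

    def __post_init__(self) -> None:
        for t, v in asdict(self).items():
            if not 0 < v < 1000:
                raise ValueError(f"emission factor {t}={v} outside (0, 1000)")

    def for_type(self, fire_type: str) -> float:
        return getattr(self, fire_type)


@dataclass(frozen=True)
class FuelModel:
    """Fitted log-linear mapping from FRP density to fuel consumption."""

    fire_type: str
    slope: float
    intercept: float
    fc_min: float            # t/ha
    fc_max: float
    fit_percentiles: tuple[float, float]
    mode: str                # "qq_linear" | "mean_match"

    def __post_init__(self) -> None:
        if self.fc_min > self.fc_max:
            raise ValueError("fc_min > fc_max")

    def predict(self, frp_density: float) -> float:
        """Fuel consumption (t/ha) at an FRP density (MW/ha), capped.

        Zero or negative density (sensor dropout, not a zero-fuel fire)
        floors at ``fc_min``.
        """
        if frp_density <= 0:
            return self.fc_min
        fc = 10.0 ** (self.intercept + self.slope * np.log10(frp_density))
        return float(min(max(fc, self.fc_min), self.fc_max))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FuelModel":
        d = json.loads(Path(path).read_text())
        d["fit_percentiles"] = tuple(d["fit_percentiles"])
        return cls(**d)


def frp_density(event: FireEvent, burned_area_km2: float) -> float:
    """Total event FRP divided by burned area, in MW per hectare."""
    if burned_area_km2 <= 0:
        raise ValueError(f"burned area must be positive, got {burned_area_km2}")
    total = sum(d.frp for d in event.detections)
    if total == 0.0:
        logger.warning(
            "event %s has zero total FRP (low-information density)", event.event_id
        )
    return total / (burned_area_km2 * HA_PER_KM2)


def _positive(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    n_zero = int((arr <= 0).sum())
    if n_zero:
        logger.info("excluding %d non-positive %s values", n_zero, label)
    return arr[arr > 0]


def fit_qq(
    field: np.ndarray,
    densities: np.ndarray,
    fire_type: str = DEFORESTATION,
    pct: tuple[float, float] = (2.0, 98.0),
) -> FuelModel:
    """Quantile–quantile calibration of FRP density to fuel consumption.

    Both empirical distributions are evaluated at the field observations'
    plotting positions ((i − 0.5)/n, linear interpolation between order
    statistics); ordinary least squares is fit on the log10 pairs whose
    density quantile lies inside the ``pct`` percentile band, and the model
    predictions at the band edges become the fuel-consumption caps.
    """
    field = _positive(field, "field fuel consumption")
    densities = _positive(densities, "FRP density")
    if len(field) < 2:
        raise FittingError("need at least 2 positive field observations")
    if len(densities) < 10:
        raise FittingError("need at least 10 positive FRP densities")
    n = len(field)
    positions = (np.arange(1, n + 1) - 0.5) / n
    fc_q = np.sort(field)  # order statistics ARE the quantiles at (i-0.5)/n
    dens_q = np.quantile(densities, positions, method="hazen")
    lo, hi = np.percentile(densities, pct, method="hazen")
    keep = (dens_q >= lo) & (dens_q <= hi)
    if keep.sum() < 2:
        raise FittingError("fewer than 2 q-q pairs inside the percentile band")
    x = np.log10(dens_q[keep])
    y = np.log10(fc_q[keep])
    slope, intercept = np.polyfit(x, y, 1)
    fc_lo = 10.0 ** (intercept + slope * np.log10(lo))
    fc_hi = 10.0 ** (intercept + slope * np.log10(hi))
    return FuelModel(
        fire_type=fire_type,
        slope=float(slope),
        intercept=float(intercept),
        fc_min=float(min(fc_lo, fc_hi)),
        fc_max=float(max(fc_lo, fc_hi)),
        fit_percentiles=(float(pct[0]), float(pct[1])),
        mode="qq_linear",
    )


def fit_mean_match(
    field_mean: float,
    densities: np.ndarray,
    fire_type: str = FOREST,
    pct: tuple[float, float] = (10.0, 90.0),
) -> FuelModel:
    """Mean-matching calibration for types with a single field observation.

    FC_i = FRPd_i × (field mean / density mean); log-space slope is 1 with
    the intercept set by the ratio.  Caps at the mapped percentile values
    of the density distribution.
    """
    if field_mean <= 0:
        raise FittingError("field mean must be positive")
    densities = _positive(densities, "FRP density")
    if len(densities) == 0:
        raise FittingError("no positive FRP densities")
    mean_d = float(densities.mean())
    if mean_d == 0:
        raise FittingError("zero mean FRP density")
    scale = field_mean / mean_d
    lo, hi = np.percentile(densities, pct, method="hazen")
    return FuelModel(
        fire_type=fire_type,
        slope=1.0,
        intercept=float(np.log10(scale)),
        fc_min=float(lo * scale),
        fc_max=float(hi * scale),
        fit_percentiles=(float(pct[0]), float(pct[1])),
        mode="mean_match",
    )


def event_emissions(
    event: FireEvent,
    burned_area_km2: float,
    model: FuelModel,
    ef: EmissionFactors | None = None,
) -> tuple[float, float]:
    """(dry matter, carbon) emitted by one event, both in Gg.

    DM [t] = burned area [ha] × fuel consumption [t/ha];
    C [t] = DM × EF / 1000 (EF in g C per kg DM).  1 Gg = 1000 t.
    """
    ef = ef or EmissionFactors()
    if event.fire_type is None:
        raise ValueError(f"event {event.event_id} has no fire type")
    if model.fire_type != event.fire_type:
        raise ValueError(
            f"fuel model for {model.fire_type!r} applied to {event.fire_type!r} event"
        )
    if burned_area_km2 < 0:
        raise ValueError("negative burned area")
    if burned_area_km2 == 0:
        return (0.0, 0.0)
    fc = model.predict(frp_density(event, burned_area_km2))
    dm_t = burned_area_km2 * HA_PER_KM2 * fc
    c_t = dm_t * ef.for_type(event.fire_type) / 1000.0
    return (dm_t / 1000.0, c_t / 1000.0)


# ---------------------------------------------------------------------------
# Packaged field fuel-consumption observations

#: literature-scale mean fuel consumption (t/ha) per fire type used by the
#: synthetic stand-in observation sets.
FIELD_MEANS = {SAVANNA: 6.5, DEFORESTATION: 95.0, SMALL: 23.0, FOREST: 40.0}
FIELD_SIZES = {SAVANNA: 8, DEFORESTATION: 19, SMALL: 4, FOREST: 1}


def default_field_observations(seed: int = 1405) -> dict[str, np.ndarray]:
    """Synthetic stand-in field fuel-consumption sets (t/ha) per fire type.

    The real compilations (8 savanna, 19 deforestation, 4 pasture, 1 forest
    measurement) are not redistributable, so lognormal draws with the same
    sample sizes and literature-scale means are packaged instead; replace
    them with a two-column CSV (fire_type, fc_t_ha) via
    :func:`read_field_observations` for production use.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    sigma = 0.45
    for fire_type in (SAVANNA, DEFORESTATION, SMALL, FOREST):
        mean, n = FIELD_MEANS[fire_type], FIELD_SIZES[fire_type]
        mu = np.log(mean) - sigma**2 / 2
        vals = np.sort(rng.lognormal(mu, sigma, size=n)) if n > 1 else np.array([mean])
        out[fire_type] = vals
    return out


def read_field_observations(path: str | Path) -> dict[str, np.ndarray]:
    """Read field fuel-consumption observations from CSV (fire_type, fc_t_ha)."""
    import pandas as pd

    df = pd.read_csv(path)
    return {
        t: g["fc_t_ha"].to_numpy(dtype=float)
        for t, g in df.groupby("fire_type")
    }
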