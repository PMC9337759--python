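"""End-to-end pipeline: grid → track → classify → scale → emit → report.

The pipeline operates on in-memory objects (a detection list, a land-cover
stack, an optional reference burned-area raster) so the same code path
serves tests, the synthetic generator, and the file-based CLI.  Without a
reference burned-area raster the burned-area calibration is skipped with a
warning: savanna and deforestation factors are downgraded to 1.0 (small
fires keep the fixed 0.1 factor, forest fires are unscaled by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import scaling as _scaling
from .classify import (
    ClassifierConfig, FireTypeResult, SAVANNA, DEFORESTATION, FOREST, SMALL,
    classify_daily, classify_event, classification_at,
)
from .detections import Detection, grid_detections
from .emissions import (
    EmissionFactors, FuelModel, default_field_observations, event_emissions,
    fit_mean_match, fit_qq, frp_density,
)
from .grid import GridSpec
from .landcover import LandCoverStack
from .metrics import event_metrics, landcover_summary
from .tracking import (
    DEFAULT_WINDOW, FireEvent, Tracker, cluster_season, filter_static_sources,
    replay_season,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window: int = DEFAULT_WINDOW
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    emission_factors: EmissionFactors = field(default_factory=EmissionFactors)
    field_observations: dict | None = None   # fire type -> fuel values (t/ha)
    nrt: bool = False                        # replay day-by-day instead of batch
    compute_daily: bool = True               # per-day classification trajectories


@dataclass
class PipelineResult:
    events: list[FireEvent]                  # kept, finalized events
    removed: list                            # (event, trigger cells) static sources
    daily: dict[int, dict[int, FireTypeResult]]
    scaling: _scaling.ScalingField | None
    fuel_models: dict[str, FuelModel]
    clusters: list


def run_pipeline(
    detections: list[Detection],
    stack: LandCoverStack,
    ba_raster: np.ndarray | None = None,
    ba_grid: GridSpec | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    grid = stack.grid

    # 1-2. grid and cluster
    cells = grid_detections(detections, grid)
    if config.nrt:
        events = replay_season(cells, window=config.window, grid=grid)
    else:
        events = cluster_season(cells, window=config.window, grid=grid)

    # 3. static-source exclusion
    events, removed = filter_static_sources(events, stack.historic_counts)

    # 4. final classification (+ optional daily trajectories)
    daily: dict[int, dict[int, FireTypeResult]] = {}
    for ev in events:
        if config.compute_daily:
            traj = classify_daily(ev, stack, config.classifier)
            daily[ev.event_id] = traj
            final = classification_at(traj, ev.end_day)
        else:
            final = classify_event(
                event_metrics(ev), landcover_summary(ev, stack), config.classifier
            )
        ev.fire_type = final.fire_type
        ev.confidence = final.confidence

    # 5. burned-area scaling
    clusters: list = []
    if ba_raster is not None:
        ba_grid = ba_grid or grid
        clusters = _scaling.cluster_reference(ba_raster, ba_grid)
        clusters = _scaling.assign_cluster_types(clusters, events, stack)
        scale_field = _scaling.fit_scaling(events, clusters, grid)
    else:
        logger.warning(
            "no reference burned-area raster: scaling skipped, savanna and "
            "deforestation factors downgraded to 1.0"
        )
        cells_05 = _scaling._study_half_cells(grid)
        scale_field = _scaling.ScalingField(
            factors={
                t: {hc: (1.0, "unscaled") for hc in cells_05}
                for t in _scaling.SCALED_TYPES
            }
        )
    for ev in events:
        ev.burned_area_km2 = _scaling.event_burned_area(ev, scale_field)

    # 6. fuel models and emissions
    field_obs = config.field_observations or default_field_observations()
    fuel_models = fit_fuel_models(events, field_obs)
    for ev in events:
        model = fuel_models.get(ev.fire_type)
        if model is None:
            ev.emissions = (0.0, 0.0)
            continue
        ev.emissions = event_emissions(
            ev, ev.burned_area_km2, model, config.emission_factors
        )
    return PipelineResult(
        events=events, removed=removed, daily=daily,
        scaling=scale_field, fuel_models=fuel_models, clusters=clusters,
    )


def fit_fuel_models(
    events: list[FireEvent], field_obs: dict
) -> dict[str, FuelModel]:
    """Per-type fuel models from event FRP densities and field observations.

    Forest fires (single field value) always use mean matching with 10–90%
    caps; the q-q fit needs at least 10 event densities, below which the
    type falls back to mean matching against the field mean (small-sample
    fallback, flagged in the log).
    """
    models: dict[str, FuelModel] = {}
    for fire_type in (SAVANNA, DEFORESTATION, SMALL, FOREST):
        evs = [e for e in events if e.fire_type == fire_type and e.burned_area_km2]
        densities = np.array(
            [frp_density(e, e.burned_area_km2) for e in evs], dtype=float
        )
        densities = densities[densities > 0]
        obs = np.asarray(field_obs.get(fire_type, ()), dtype=float)
        if obs.size == 0 or densities.size == 0:
            continue
        if fire_type != FOREST and obs.size >= 2 and densities.size >= 10:
            models[fire_type] = fit_qq(obs, densities, fire_type=fire_type)
        else:
            if fire_type != FOREST:
                logger.info(
                    "%s: %d densities below q-q minimum, using mean matching",
                    fire_type, densities.size,
                )
            models[fire_type] = fit_mean_match(
                float(obs.mean()), densities, fire_type=fire_type
            )
    return models
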