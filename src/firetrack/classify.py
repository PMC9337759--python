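"""Rule-based daily fire-type classification with confidence levels.

Each fire event is assigned one of four types — ``savanna`` (grassland and
open woodland), ``deforestation`` (burning of felled forest and piled
debris), ``small`` (short-lived clearing/agricultural management fires) and
``forest`` (understory fires beneath intact canopy) — with a ``high`` /
``medium`` / ``low`` confidence.  The decision flow, evaluated daily on
cumulative per-event averages:

1. mean 2014 tree cover < 50%  →  savanna; confidence from the tree-cover
   band (high < 20%, medium 20–40%, low 40–50%);
2. ≥ 25% of footprint cells flagged as historic deforestation
   (trailing 5-year window)  →  deforestation, high confidence;
3. not a "large" fire (> 5 detections AND mean persistence > 1 day)
   →  small, high confidence;
4. large fires split by a 120 t/ha biomass threshold into a *moist* regime,
   where high mean FRP alone marks high-confidence deforestation, and a
   *dry* regime, where high persistence does; then fires > 100 km² are
   high-confidence forest fires; everything left goes to a five-indicator
   vote (FRP, persistence, day fraction, size < 40 km², detection density)
   counting deforestation points 0–5, mapped to type and confidence.

In the dry regime fire behavior inverts for two indicators: dry-forest
fires resemble savanna fires (higher FRP, pronounced daytime diurnal
cycle), so there high FRP and high day fraction vote *forest* and their
absence votes deforestation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .metrics import FireBehaviorMetrics, LandCoverSummary, event_metrics, landcover_summary
from .landcover import LandCoverStack
from .tracking import FireEvent

DEFORESTATION = "deforestation"
FOREST = "forest"
SMALL = "small"
SAVANNA = "savanna"
FIRE_TYPES = (DEFORESTATION, FOREST, SMALL, SAVANNA)

HIGH, MEDIUM, LOW = "high", "medium", "low"

#: score (deforestation points) -> (fire type, confidence)
DEFAULT_SCORE_BANDS: dict[int, tuple[str, str]] = {
    5: (DEFORESTATION, HIGH),
    4: (DEFORESTATION, MEDIUM),
    3: (DEFORESTATION, LOW),
    2: (FOREST, LOW),
    1: (FOREST, MEDIUM),
    0: (FOREST, HIGH),
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """All classifier thresholds; every value is config-exposed.

    The indicator cutpoints ``frp_high`` (MW), ``persistence_high`` (days),
    ``day_fraction_high`` and ``density_high`` (detections/km²) separate
    deforestation-like from forest-like behavior in the five-indicator
    vote; their defaults reflect the contrast between deforestation fires
    (mean FRP ≈ 15–16 MW, multiday in-place burning) and understory forest
    fires (≈ 10–12 MW, > 10 detections/km² of burned area).
    """

    tree_cover_split: float = 50.0       # % tree cover separating savanna
    savanna_high_max: float = 20.0       # high-confidence savanna below this
    savanna_medium_max: float = 40.0     # medium 20-40, low 40-50
    hist_defor_threshold: float = 0.25   # footprint fraction
    small_max_detections: int = 5
    small_max_persistence: float = 1.0   # days
    biomass_split: float = 120.0         # t/ha moist vs dry regime
    size_defor_km2: float = 40.0         # below: size votes deforestation
    size_forest_km2: float = 100.0       # above: high-confidence forest
    frp_high: float = 15.0               # MW
    persistence_high: float = 2.0        # days
    day_fraction_high: float = 0.7
    density_high: float = 10.0           # detections / km2
    score_bands: tuple[tuple[int, tuple[str, str]], ...] = tuple(
        sorted(DEFAULT_SCORE_BANDS.items())
    )

    def __post_init__(self) -> None:
        bands = dict(self.score_bands)
        if sorted(bands) != list(range(6)):
            raise ConfigurationError(
                f"score bands must cover 0..5 exactly, got {sorted(bands)}"
            )
        if not (0 < self.savanna_high_max <= self.savanna_medium_max <= self.tree_cover_split):
            raise ConfigurationError("savanna confidence bands must be nested")

    def band(self, score: int) -> tuple[str, str]:
        return dict(self.score_bands)[score]

    # -- plain-text (key = value) round trip --------------------------------
    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                if key == "score_bands":
                    val = ";".join(f"{s}:{t},{c}" for s, (t, c) in self.score_bands)
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassifierConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "score_bands":
                bands = []
                for part in val.split(";"):
                    s, tc = part.split(":")
                    t, c = tc.split(",")
                    bands.append((int(s), (t.strip(), c.strip())))
                kwargs[key] = tuple(sorted(bands))
            elif key in ("small_max_detections",):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass(frozen=True)
class FireTypeResult:
    fire_type: str
    confidence: str
    score: int | None = None           # set only when the vote decided
    rule_path: tuple[str, ...] = ()


def score_indicators(
    m: FireBehaviorMetrics, regime: str, cfg: ClassifierConfig
) -> int:
    """Count deforestation votes (0–5) from the five behavior indicators."""
    if regime not in ("moist", "dry"):
        raise ValueError(f"unknown regime {regime!r}")
    dry = regime == "dry"
    votes = [
        # FRP: high FRP is deforestation-like in moist forest, savanna-like
        # (hence forest-vote) in dry forest
        (m.mean_frp < cfg.frp_high) if dry else (m.mean_frp >= cfg.frp_high),
        m.mean_persistence >= cfg.persistence_high,
        # day fraction: pronounced diurnal cycle marks dry forest fires
        (m.day_fraction < cfg.day_fraction_high) if dry
        else (m.day_fraction >= cfg.day_fraction_high),
        m.size_km2 < cfg.size_defor_km2,
        m.detection_density < cfg.density_high,
    ]
    return int(sum(votes))


def classify_event(
    m: FireBehaviorMetrics,
    lc: LandCoverSummary,
    cfg: ClassifierConfig | None = None,
) -> FireTypeResult:
    """Classify one event (or one cumulative daily snapshot of it)."""
    cfg = cfg or ClassifierConfig()
    path: list[str] = []

    # 1. open-cover types
    if lc.mean_tree_cover_2014 < cfg.tree_cover_split:
        path.append(f"tree_cover<{cfg.tree_cover_split}")
        tc = lc.mean_tree_cover_2014
        if tc < cfg.savanna_high_max:
            conf = HIGH
        elif tc < cfg.savanna_medium_max:
            conf = MEDIUM
        else:
            conf = LOW
        path.append(f"savanna_band:{conf}")
        return FireTypeResult(SAVANNA, conf, rule_path=tuple(path))
    path.append(f"tree_cover>={cfg.tree_cover_split}")

    # 2. historic deforestation overlap
    if lc.historic_deforestation_fraction >= cfg.hist_defor_threshold:
        path.append(f"hist_defor>={cfg.hist_defor_threshold}")
        return FireTypeResult(DEFORESTATION, HIGH, rule_path=tuple(path))

    # 3. small clearing / agricultural fires: complement of "large"
    if not (
        m.n_detections > cfg.small_max_detections
        and m.mean_persistence > cfg.small_max_persistence
    ):
        path.append(
            f"small:n<={cfg.small_max_detections} or "
            f"persistence<={cfg.small_max_persistence}"
        )
        return FireTypeResult(SMALL, HIGH, rule_path=tuple(path))
    path.append("large_fire")

    # 4. large-fire branch: moist vs dry regime primary indicators
    regime = "moist" if lc.mean_biomass >= cfg.biomass_split else "dry"
    path.append(f"regime:{regime}")
    if regime == "moist" and m.mean_frp >= cfg.frp_high:
        path.append(f"frp>={cfg.frp_high}")
        return FireTypeResult(DEFORESTATION, HIGH, rule_path=tuple(path))
    if regime == "dry" and m.mean_persistence >= cfg.persistence_high:
        path.append(f"persistence>={cfg.persistence_high}")
        return FireTypeResult(DEFORESTATION, HIGH, rule_path=tuple(path))
    if m.size_km2 > cfg.size_forest_km2:
        path.append(f"size>{cfg.size_forest_km2}km2")
        return FireTypeResult(FOREST, HIGH, rule_path=tuple(path))

    score = score_indicators(m, regime, cfg)
    fire_type, conf = cfg.band(score)
    path.append(f"vote:{score}")
    return FireTypeResult(fire_type, conf, score=score, rule_path=tuple(path))


def classify_daily(
    event: FireEvent,
    stack: LandCoverStack,
    cfg: ClassifierConfig | None = None,
) -> dict[int, FireTypeResult]:
    """Near-real-time trajectory: classification for every day of the event.

    Cumulative metrics only change on active days; intermediate days carry
    the last active day's result forward.
    """
    cfg = cfg or ClassifierConfig()
    out: dict[int, FireTypeResult] = {}
    last: FireTypeResult | None = None
    active = set(event.active_days)
    for day in range(event.start_day, event.end_day + 1):
        if day in active or last is None:
            m = event_metrics(event, upto_day=day)
            lc = landcover_summary(event, stack, upto_day=day)
            last = classify_event(m, lc, cfg)
        out[day] = last
    return out


def classification_at(
    daily: dict[int, FireTypeResult], day: int
) -> FireTypeResult:
    """Result in effect on ``day``: clamped to the trajectory's range."""
    days = sorted(daily)
    if day <= days[0]:
        return daily[days[0]]
    if day >= days[-1]:
        return daily[days[-1]]
    return daily[day]


def lag_agreement(
    events: list[FireEvent],
    daily: dict[int, dict[int, FireTypeResult]],
    final: dict[int, str] | None = None,
    lags: tuple[int, ...] = (1, 2, 7),
) -> pd.DataFrame:
    """Near-real-time accuracy: do early labels match the final type?

    For each lag ``L``, each detection is scored against its event's
    classification after ``L`` days of observations (the cumulative daily
    result on day ``start_day + L - 1``).  Returns a tidy frame
    with columns ``lag, day, fire_type, n_detections, n_matched`` —
    detection-weighted per calendar day; aggregate with
    :func:`aggregate_lag_agreement`.  Days with no detections of a type are
    simply absent (undefined, not zero).
    """
    if final is None:
        final = {
            ev.event_id: classification_at(daily[ev.event_id], ev.end_day).fire_type
            for ev in events
        }
    rows: list[tuple[int, int, str, int, int]] = []
    counts: dict[tuple[int, int, str], list[int]] = {}
    for ev in events:
        traj = daily[ev.event_id]
        ftype = final[ev.event_id]
        for lag in lags:
            lag_type = classification_at(traj, ev.start_day + lag - 1).fire_type
            match = int(lag_type == ftype)
            for det in ev.detections:
                key = (lag, det.acq_day, ftype)
                cnt = counts.setdefault(key, [0, 0])
                cnt[0] += 1
                cnt[1] += match
    for (lag, day, ftype), (n, matched) in sorted(counts.items()):
        rows.append((lag, day, ftype, n, matched))
    return pd.DataFrame(
        rows, columns=["lag", "day", "fire_type", "n_detections", "n_matched"]
    )


def aggregate_lag_agreement(table: pd.DataFrame) -> pd.DataFrame:
    """Season-aggregate matched fraction per (lag, fire_type) plus 'all'."""
    per_type = (
        table.groupby(["lag", "fire_type"])[["n_detections", "n_matched"]]
        .sum()
        .reset_index()
    )
    overall = (
        table.groupby("lag")[["n_detections", "n_matched"]].sum().reset_index()
    )
    overall["fire_type"] = "all"
    out = pd.concat([per_type, overall], ignore_index=True)
    out["fraction"] = out["n_matched"] / out["n_detections"]
    return out


DURATION_CLASSES = ("1 day", "2-10 days", ">10 days")


def duration_class(duration: int) -> str:
    if duration <= 1:
        return DURATION_CLASSES[0]
    if duration <= 10:
        return DURATION_CLASSES[1]
    return DURATION_CLASSES[2]


def duration_classes(events: list[FireEvent]) -> pd.DataFrame:
    """Per-day detection fractions by final event duration class.

    Columns: ``day`` plus one fraction per class; fractions sum to 1 on
    every day with detections.
    """
    counts: dict[int, dict[str, int]] = {}
    for ev in events:
        cls = duration_class(ev.duration)
        for det in ev.detections:
            day_counts = counts.setdefault(det.acq_day, dict.fromkeys(DURATION_CLASSES, 0))
            day_counts[cls] += 1
    rows = []
    for day in sorted(counts):
        total = sum(counts[day].values())
        rows.append(
            {"day": day, **{c: counts[day][c] / total for c in DURATION_CLASSES}}
        )
    return pd.DataFrame(rows, columns=["day", *DURATION_CLASSES])
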