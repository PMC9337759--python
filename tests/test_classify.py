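"""Fire-type decision flow, five-indicator vote, daily trajectories and
near-real-time lag evaluation."""

import numpy as np
import pytest

from firetrack.classify import (
    ClassifierConfig, ConfigurationError, DEFORESTATION, FOREST, SAVANNA, SMALL,
    aggregate_lag_agreement, classify_daily, classify_event, classification_at,
    duration_classes, lag_agreement, score_indicators,
)
from firetrack.metrics import FireBehaviorMetrics, LandCoverSummary, event_metrics, landcover_summary

from util import SMALL_GRID, build_event

CFG = ClassifierConfig()


def metrics(
    n=100, frp=10.0, day_frac=0.5, persistence=2.0, duration=5, size=10.0, density=None
):
    return FireBehaviorMetrics(
        n_detections=n,
        mean_frp=frp,
        day_fraction=day_frac,
        mean_persistence=persistence,
        duration=duration,
        size_km2=size,
        detection_density=density if density is not None else n / size,
    )


def landcover(tc=70.0, hist=0.0, biomass=200.0):
    return LandCoverSummary(
        mean_tree_cover_2014=tc,
        historic_deforestation_fraction=hist,
        mean_biomass=biomass,
    )


class TestDecisionFlow:
    def test_savanna_medium_band(self):
        res = classify_event(metrics(), landcover(tc=30.0), CFG)
        assert (res.fire_type, res.confidence) == (SAVANNA, "medium")

    @pytest.mark.parametrize(
        "tc,conf", [(5.0, "high"), (19.99, "high"), (20.0, "medium"),
                    (39.99, "medium"), (40.0, "low"), (49.99, "low")]
    )
    def test_savanna_confidence_bands(self, tc, conf):
        res = classify_event(metrics(), landcover(tc=tc), CFG)
        assert (res.fire_type, res.confidence) == (SAVANNA, conf)

    def test_historic_deforestation_high(self):
        res = classify_event(metrics(), landcover(tc=70.0, hist=0.30), CFG)
        assert (res.fire_type, res.confidence) == (DEFORESTATION, "high")
        assert res.score is None

    def test_small_fire(self):
        res = classify_event(metrics(n=4, persistence=1.0), landcover(tc=70.0), CFG)
        assert (res.fire_type, res.confidence) == (SMALL, "high")

    def test_small_by_persistence_alone(self):
        # many detections but single-day persistence is still "small"
        res = classify_event(metrics(n=50, persistence=1.0), landcover(tc=70.0), CFG)
        assert res.fire_type == SMALL

    def test_large_forest_fire_by_size(self):
        res = classify_event(
            metrics(n=200, frp=8.0, persistence=4.0, size=150.0),
            landcover(tc=70.0, biomass=200.0),
            CFG,
        )
        # moist regime: low FRP avoids the deforestation shortcut; size > 100
        assert (res.fire_type, res.confidence) == (FOREST, "high")

    def test_moist_high_frp_is_deforestation(self):
        res = classify_event(
            metrics(n=50, frp=18.0, persistence=3.0), landcover(biomass=200.0), CFG
        )
        assert (res.fire_type, res.confidence) == (DEFORESTATION, "high")

    def test_dry_high_persistence_is_deforestation(self):
        res = classify_event(
            metrics(n=50, frp=8.0, persistence=3.0), landcover(biomass=80.0), CFG
        )
        assert (res.fire_type, res.confidence) == (DEFORESTATION, "high")

    def test_vote_saturation_deforestation(self):
        # all five indicators in the deforestation direction give score 5,
        # which the bands map to high-confidence deforestation; the full
        # decision flow reaches the same outcome through its primary rules
        m = metrics(n=50, frp=5.0, day_frac=0.3, persistence=3.0, size=10.0, density=5.0)
        assert score_indicators(m, "dry", CFG) == 5
        assert CFG.band(5) == (DEFORESTATION, "high")
        res = classify_event(m, landcover(biomass=80.0), CFG)
        assert (res.fire_type, res.confidence) == (DEFORESTATION, "high")

    def test_vote_saturation_forest(self):
        m = metrics(n=500, frp=8.0, day_frac=0.3, persistence=1.5, size=60.0, density=12.0)
        res = classify_event(m, landcover(biomass=200.0), CFG)
        assert res.score == 0
        assert (res.fire_type, res.confidence) == (FOREST, "high")

    def test_rule_path_always_populated(self):
        res = classify_event(metrics(), landcover(tc=10.0), CFG)
        assert res.rule_path


class TestScoreIndicators:
    @pytest.mark.parametrize("seed", range(20))
    def test_vote_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = metrics(
            n=int(rng.integers(6, 500)),
            frp=float(rng.uniform(1, 40)),
            day_frac=float(rng.uniform(0, 1)),
            persistence=float(rng.uniform(1, 6)),
            size=float(rng.uniform(1, 200)),
            density=float(rng.uniform(0.5, 30)),
        )
        for regime in ("moist", "dry"):
            score = score_indicators(m, regime, CFG)
            # independent recount
            expected = 0
            if regime == "moist":
                expected += m.mean_frp >= 15.0
                expected += m.day_fraction >= 0.7
            else:
                expected += m.mean_frp < 15.0
                expected += m.day_fraction < 0.7
            expected += m.mean_persistence >= 2.0
            expected += m.size_km2 < 40.0
            expected += m.detection_density < 10.0
            assert score == int(expected)
            assert 0 <= score <= 5

    def test_threshold_continuity(self):
        """Perturbing one metric across its threshold changes the score by
        at most one."""
        base = metrics(n=50, frp=14.999, day_frac=0.5, persistence=1.5, size=50.0, density=12.0)
        bumped = metrics(n=50, frp=15.001, day_frac=0.5, persistence=1.5, size=50.0, density=12.0)
        assert abs(
            score_indicators(base, "moist", CFG) - score_indicators(bumped, "moist", CFG)
        ) == 1


class TestConfig:
    def test_inconsistent_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierConfig(score_bands=((0, (FOREST, "high")),))

    def test_file_round_trip(self, tmp_path):
        cfg = ClassifierConfig(frp_high=17.5, small_max_detections=7)
        p = tmp_path / "classifier.cfg"
        cfg.to_file(p)
        assert ClassifierConfig.from_file(p) == cfg


class TestClassifyDaily:
    def _stack(self, tc_cols):
        import numpy as np
        from firetrack.landcover import LandCoverStack

        shape = SMALL_GRID.shape
        rows, cols = np.indices(shape)
        tc = np.select(
            [cols < b for b in tc_cols["breaks"]], tc_cols["values"][:-1],
            tc_cols["values"][-1],
        )
        return LandCoverStack(
            grid=SMALL_GRID,
            tree_cover_2000=tc.astype(float),
            loss_year=np.zeros(shape, int),
            historic_deforestation=np.zeros(shape, bool),
            biomass=np.full(shape, 200.0),
        )

    def test_single_day_small_fire(self):
        ev = build_event(SMALL_GRID, {(0, 0): [200]})
        stack = self._stack({"breaks": [1000], "values": [70.0, 70.0]})
        daily = classify_daily(ev, stack, CFG)
        assert list(daily) == [200]
        assert daily[200].fire_type == SMALL

    def test_savanna_to_forest_transition(self):
        """An event igniting in savanna and growing into forest flips type
        once the mean tree cover crosses 50%."""
        cells_days = {(0, c): [200 + c] for c in range(5)}
        ev = build_event(SMALL_GRID, cells_days, per_day=3)
        # first 2 columns savanna (20%), the rest forest (90%)
        stack = self._stack({"breaks": [2], "values": [20.0, 90.0]})
        daily = classify_daily(ev, stack, CFG)
        assert daily[200].fire_type == SAVANNA
        assert daily[204].fire_type != SAVANNA
        # mean tc over 5 cells: (2*20 + 3*90)/5 = 62 -> forest branch
        types = [daily[d].fire_type for d in sorted(daily)]
        assert types == sorted(types, key=lambda t: t == SAVANNA, reverse=True)

    def test_final_day_equals_batch_classification(self, default_season, default_result):
        for ev in default_result.events[:10]:
            daily = default_result.daily[ev.event_id]
            final = classify_event(
                event_metrics(ev), landcover_summary(ev, default_season.stack), CFG
            )
            assert classification_at(daily, ev.end_day).fire_type == final.fire_type


class TestLagAgreement:
    def test_all_single_type_from_day_one(self):
        evs = [build_event(SMALL_GRID, {(0, 0): [200]}, event_id=0)]
        daily = {0: {200: classify_event(metrics(n=1, persistence=1), landcover(), CFG)}}
        table = lag_agreement(evs, daily)
        agg = aggregate_lag_agreement(table)
        assert (agg["fraction"] == 1.0).all()

    def test_hand_counted_fixture(self):
        """10 detections on one day; one 2-detection event wrong at 1-day
        lag only -> day-1 overall fraction 0.8."""
        from firetrack.classify import FireTypeResult

        ev_good = build_event(SMALL_GRID, {(0, c): [200] for c in range(8)}, event_id=0)
        ev_bad = build_event(SMALL_GRID, {(9, 0): [200]}, event_id=1, per_day=2)
        good_final = FireTypeResult(SMALL, "high")
        bad_wrong = FireTypeResult(SAVANNA, "high")
        bad_final = FireTypeResult(SMALL, "high")
        daily = {
            0: {200: good_final},
            1: {200: bad_wrong, 201: bad_final},
        }
        table = lag_agreement(
            [ev_good, ev_bad], daily, final={0: SMALL, 1: SMALL}, lags=(1, 2)
        )
        day200_lag1 = table[(table.lag == 1) & (table.day == 200)]
        assert day200_lag1.n_detections.sum() == 10
        assert day200_lag1.n_matched.sum() == 8
        day200_lag2 = table[(table.lag == 2) & (table.day == 200)]
        assert day200_lag2.n_matched.sum() == 10

    def test_monotone_in_lag_on_synthetic_seasons(self, default_result):
        agg = aggregate_lag_agreement(
            lag_agreement(default_result.events, default_result.daily)
        )
        overall = agg[agg.fire_type == "all"].sort_values("lag")["fraction"].tolist()
        assert overall == sorted(overall)


class TestDurationClasses:
    def test_all_single_day(self):
        evs = [build_event(SMALL_GRID, {(0, 0): [200]}, event_id=0)]
        table = duration_classes(evs)
        assert (table["1 day"] == 1.0).all()

    def test_long_event_only(self):
        evs = [build_event(SMALL_GRID, {(0, 0): [200, 212]}, event_id=0)]
        table = duration_classes(evs)
        assert (table[">10 days"] == 1.0).all()

    def test_fractions_sum_to_one(self, default_result):
        table = duration_classes(default_result.events)
        sums = table[["1 day", "2-10 days", ">10 days"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
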