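"""Burned-area reference clustering, cluster typing, and the region-growing
scaling-factor fit."""

import numpy as np
import pytest

from firetrack.classify import DEFORESTATION, FOREST, SAVANNA, SMALL
from firetrack.grid import GridSpec
from firetrack.landcover import LandCoverStack
from firetrack.scaling import (
    RESIDUAL, BurnCluster, ScalingError, assign_cluster_types, cluster_reference,
    event_burned_area, fit_scaling, half_cell,
)

from util import SMALL_GRID, build_event

GRID = SMALL_GRID  # 100x100 cells, 0.5deg x 0.5deg -> exactly one 0.5deg cell


def uniform_stack(tc):
    shape = GRID.shape
    return LandCoverStack(
        grid=GRID,
        tree_cover_2000=np.full(shape, float(tc)),
        loss_year=np.zeros(shape, int),
        historic_deforestation=np.zeros(shape, bool),
        biomass=np.full(shape, 150.0),
    )


class TestClusterReference:
    def test_two_patches_separated_by_unburned_row(self):
        ba = np.zeros(GRID.shape)
        ba[0:2, 0:3] = 210
        ba[4:6, 0:3] = 215
        clusters = cluster_reference(ba, GRID)
        assert len(clusters) == 2

    def test_single_cell_cluster(self):
        ba = np.zeros(GRID.shape)
        ba[10, 10] = 200
        (cl,) = cluster_reference(ba, GRID)
        assert cl.cells == [(10, 10)]
        assert cl.area_km2 == pytest.approx(GRID.cell_area_km2((10, 10)))

    def test_all_zero_raster(self):
        assert cluster_reference(np.zeros(GRID.shape), GRID) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ba = (rng.random((30, 30)) < 0.3) * 200.0
        grid = GridSpec(extent=(0.0, 0.0, 0.15, 0.15), res=0.005)
        clusters = cluster_reference(ba, grid)
        # independent BFS flood fill
        burned = {tuple(c) for c in np.argwhere(ba > 0)}
        comps = set()
        seen = set()
        for start in sorted(burned):
            if start in seen:
                continue
            comp, stack = {start}, [start]
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nb = (r + dr, c + dc)
                        if nb in burned and nb not in comp:
                            comp.add(nb)
                            stack.append(nb)
            seen |= comp
            comps.add(frozenset(comp))
        assert {frozenset(cl.cells) for cl in clusters} == comps


class TestAssignClusterTypes:
    def test_dominant_overlap_wins(self):
        defor = build_event(GRID, {(0, c): [200] for c in range(3)}, event_id=0)
        defor.fire_type = DEFORESTATION
        sav = build_event(GRID, {(0, c): [200] for c in range(3, 5)}, event_id=1)
        sav.fire_type = SAVANNA
        ba = np.zeros(GRID.shape)
        ba[0, 0:5] = 210
        clusters = cluster_reference(ba, GRID)
        assign_cluster_types(clusters, [defor, sav])
        assert clusters[0].fire_type == DEFORESTATION

    def test_tie_breaks_to_earlier_ignition(self):
        a = build_event(GRID, {(0, 0): [205]}, event_id=0)
        a.fire_type = SAVANNA
        b = build_event(GRID, {(0, 1): [200]}, event_id=1)
        b.fire_type = FOREST
        ba = np.zeros(GRID.shape)
        ba[0, 0:2] = 210
        clusters = assign_cluster_types(cluster_reference(ba, GRID), [a, b])
        assert clusters[0].fire_type == FOREST  # event b ignited earlier

    def test_unmatched_low_tree_cover_is_savanna(self):
        ba = np.zeros(GRID.shape)
        ba[50, 50] = 220
        clusters = assign_cluster_types(
            cluster_reference(ba, GRID), [], stack=uniform_stack(30.0)
        )
        assert clusters[0].fire_type == SAVANNA

    def test_unmatched_high_tree_cover_is_residual(self):
        ba = np.zeros(GRID.shape)
        ba[50, 50] = 220
        clusters = assign_cluster_types(
            cluster_reference(ba, GRID), [], stack=uniform_stack(80.0)
        )
        assert clusters[0].fire_type == RESIDUAL


def typed_event(cells, fire_type, event_id=0, day=200):
    ev = build_event(GRID, {c: [day] for c in cells}, event_id=event_id)
    ev.fire_type = fire_type
    return ev


def block(r0, c0, n):
    """n x n block of cells."""
    return [(r, c) for r in range(r0, r0 + n) for c in range(c0, c0 + n)]


class TestFitScaling:
    def test_identity_factor_at_native_level(self):
        # one 0.5 deg cell with equal (~76 km2) footprint and reference area
        cells = block(10, 10, 16)
        ev = typed_event(cells, SAVANNA)
        cl = BurnCluster(0, cells, GRID, fire_type=SAVANNA)
        field = fit_scaling([ev], [cl], GRID)
        hc = half_cell(*ev.ignition_lonlat)
        factor, level = field.factors[SAVANNA][hc]
        assert factor == pytest.approx(1.0, abs=1e-12)
        assert level == "0.5deg"

    def test_pooled_ratio_after_aggregation(self):
        """Two 0.5 deg cells each below the 50 km2 support resolve at 1 deg
        with the pooled ratio."""
        grid = GridSpec(extent=(0.0, 0.0, 1.0, 0.5), res=0.005)

        def ev_at(c0, n, eid):
            ev = build_event(grid, {c: [200] for c in block(10, c0, n)}, event_id=eid)
            ev.fire_type = SAVANNA
            return ev

        ev_a = ev_at(10, 9, 0)       # ~25 km2 in western 0.5 cell
        ev_b = ev_at(110, 11, 1)     # ~37 km2 in eastern 0.5 cell
        # reference: clusters over the same cells with area override
        foot_a = ev_a.size_km2
        foot_b = ev_b.size_km2
        cl_a = BurnCluster(0, sorted(ev_a.footprint), grid, SAVANNA,
                           area_override_km2=30.0)
        cl_b = BurnCluster(1, sorted(ev_b.footprint), grid, SAVANNA,
                           area_override_km2=42.0)
        field = fit_scaling([ev_a, ev_b], [cl_a, cl_b], grid)
        expected = (30.0 + 42.0) / (foot_a + foot_b)
        for hc in field.factors[SAVANNA]:
            factor, level = field.factors[SAVANNA][hc]
            assert level == "1.0deg"
            assert factor == pytest.approx(expected, rel=1e-12)

    def test_constructed_proportionality_recovers_factor(self):
        """Reference = 0.8 x footprint everywhere -> every factor is 0.8."""
        events, clusters = [], []
        for i, (r0, c0) in enumerate([(5, 5), (30, 30), (60, 60)]):
            cells = block(r0, c0, 12)
            ev = typed_event(cells, DEFORESTATION, event_id=i)
            events.append(ev)
            clusters.append(
                BurnCluster(i, cells, GRID, DEFORESTATION,
                            area_override_km2=0.8 * ev.size_km2)
            )
        field = fit_scaling(events, clusters, GRID)
        for factor, _ in field.factors[DEFORESTATION].values():
            assert factor == pytest.approx(0.8, abs=1e-12)

    def test_conservation_at_native_level(self):
        """Within a natively resolved 0.5 deg cell, summed scaled burned area
        equals the reference burned area."""
        ev1 = typed_event(block(10, 10, 12), SAVANNA, event_id=0)
        ev2 = typed_event(block(40, 40, 10), SAVANNA, event_id=1)
        ref_cells = block(10, 10, 14) + block(60, 60, 8)
        cl = BurnCluster(0, sorted(set(ref_cells)), GRID, SAVANNA)
        field = fit_scaling([ev1, ev2], [cl], GRID)
        scaled = sum(event_burned_area(e, field) for e in (ev1, ev2))
        assert scaled == pytest.approx(cl.area_km2, rel=1e-9)

    def test_zero_footprint_nonzero_reference_errors(self):
        cl = BurnCluster(0, block(10, 10, 20), GRID, SAVANNA)
        with pytest.raises(ScalingError):
            fit_scaling([], [cl], GRID)

    def test_no_data_gives_neutral_continental_factor(self):
        field = fit_scaling([], [], GRID)
        for t in (SAVANNA, DEFORESTATION):
            for factor, level in field.factors[t].values():
                assert factor == 1.0 and level == "continental"

    def test_order_invariance(self):
        events = [
            typed_event(block(5, 5, 10), SAVANNA, event_id=0),
            typed_event(block(40, 40, 10), SAVANNA, event_id=1),
        ]
        cl = BurnCluster(0, block(5, 5, 12), GRID, SAVANNA)
        f1 = fit_scaling(events, [cl], GRID)
        f2 = fit_scaling(events[::-1], [cl], GRID)
        assert f1.factors == f2.factors


class TestEventBurnedArea:
    def _field(self, factor=1.3):
        cells = {half_cell(0.25, 0.25): (factor, "0.5deg")}
        from firetrack.scaling import ScalingField

        return ScalingField(factors={SAVANNA: dict(cells), DEFORESTATION: dict(cells)})

    def test_small_fire_fixed_factor(self):
        ev = typed_event([(0, 0), (0, 1)], SMALL)
        assert event_burned_area(ev, self._field()) == pytest.approx(
            ev.size_km2 * 0.1
        )

    def test_forest_fire_unscaled(self):
        ev = typed_event(block(0, 0, 5), FOREST)
        assert event_burned_area(ev, self._field()) == pytest.approx(ev.size_km2)

    def test_savanna_local_factor(self):
        ev = typed_event(block(0, 0, 4), SAVANNA)
        assert event_burned_area(ev, self._field(1.3)) == pytest.approx(
            ev.size_km2 * 1.3
        )

    def test_untyped_event_errors(self):
        ev = build_event(GRID, {(0, 0): [200]})
        with pytest.raises(ScalingError):
            event_burned_area(ev, self._field())
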