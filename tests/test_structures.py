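"""Parametric culture-dish structure generators and face counting."""

import math
import random

import pytest

from petripath import (
    ConicalWellSpec,
    DoubleRingSpec,
    GridSpec,
    MultiWellDishSpec,
    Position,
    PrintSettings,
    RingSpec,
    StructureError,
    ToolpathBuilder,
    build_conical_well,
    build_double_ring,
    build_ring,
    build_seven_well_dish,
    build_sorter_grid,
    count_enclosed_cells,
)

from conftest import extrusion_segments, layer_radii, raster_enclosed_regions, square_polyline


class TestRing:
    def test_default_ring_has_15_layers(self):
        zs = sorted(layer_radii(build_ring(RingSpec())))
        assert len(zs) == 15  # 1.8 mm at 0.12 mm layers

    def test_layer_z_strictly_increasing_multiples_of_layer_height(self, settings):
        zs = sorted(layer_radii(build_ring(RingSpec())))
        for k, z in enumerate(zs, start=1):
            assert z == pytest.approx(k * settings.layer_height, abs=1e-9)

    def test_every_layer_closed(self):
        ring = build_ring(RingSpec())
        by_z: dict[float, list] = {}
        for s in extrusion_segments(ring):
            by_z.setdefault(round(s.end.z, 9), []).append(s)
        for segs in by_z.values():
            first, last = segs[0].start, segs[-1].end
            assert first.distance_to(last) <= 1e-9

    def test_radial_extent_is_half_diameter(self):
        radii = layer_radii(build_ring(RingSpec(diameter=6.0)))
        for r in radii.values():
            assert r == pytest.approx(3.0, abs=1e-8)

    def test_tiny_diameter_rejected(self):
        with pytest.raises(StructureError):
            build_ring(RingSpec(diameter=0.3))  # below the 0.4 mm nozzle


class TestConicalWell:
    def test_cylindrical_section_constant_radius(self):
        spec = ConicalWellSpec()
        radii = layer_radii(build_conical_well(spec))
        for z, r in radii.items():
            if z <= spec.wall_height + 1e-9:
                assert r == pytest.approx(spec.base_radius, abs=1e-8)

    def test_top_minus_base_radius(self):
        spec = ConicalWellSpec()
        radii = layer_radii(build_conical_well(spec))
        expected = spec.cone_height * math.tan(math.radians(50.0))  # ~1.1918 mm
        zs = sorted(radii)
        assert radii[zs[-1]] - radii[zs[0]] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1.1918, abs=1e-4)

    def test_apex_angle_recovered_from_layer_radii(self):
        spec = ConicalWellSpec()
        radii = layer_radii(build_conical_well(spec))
        cone = sorted(
            (z, r)
            for z, r in radii.items()
            if spec.wall_height + 1e-9 < z <= spec.total_height + 1e-9
        )
        assert len(cone) >= 2
        (z1, r1), (z2, r2) = cone[0], cone[-1]
        angle = 2.0 * math.degrees(math.atan((r2 - r1) / (z2 - z1)))
        assert angle == pytest.approx(100.0, abs=0.1)

    def test_radius_vs_z_piecewise_linear_in_cone(self):
        spec = ConicalWellSpec()
        radii = layer_radii(build_conical_well(spec))
        slope = math.tan(math.radians(spec.apex_angle / 2.0))
        for z, r in radii.items():
            if spec.wall_height < z <= spec.total_height:
                assert r == pytest.approx(
                    spec.base_radius + (z - spec.wall_height) * slope, abs=1e-9
                )

    def test_flat_apex_angle_rejected(self):
        with pytest.raises(StructureError):
            ConicalWellSpec(apex_angle=180.0)


class TestSevenWellDish:
    def test_seven_disjoint_well_footprints(self):
        spec = MultiWellDishSpec()
        centers = spec.well_centers()
        assert len(centers) == 7
        top_r = spec.well.top_radius
        for i, (xi, yi) in enumerate(centers):
            for xj, yj in centers[i + 1 :]:
                assert math.hypot(xi - xj, yi - yj) >= 2.0 * top_r - 1e-9

    def test_all_extrusion_inside_35mm_dish(self):
        dish = build_seven_well_dish(MultiWellDishSpec())
        for s in extrusion_segments(dish):
            for p in (s.start, s.end):
                assert math.hypot(p.x, p.y) <= 17.5 + 1e-8

    def test_pairwise_center_distance_at_least_top_diameter(self):
        spec = MultiWellDishSpec()
        top_d = 2.0 * spec.well.top_radius
        centers = spec.well_centers()
        for i, (xi, yi) in enumerate(centers):
            for xj, yj in centers[i + 1 :]:
                assert math.hypot(xi - xj, yi - yj) >= top_d - 1e-9

    def test_oversized_wells_rejected(self):
        with pytest.raises(StructureError):
            build_seven_well_dish(
                MultiWellDishSpec(well=ConicalWellSpec(base_diameter=12.0))
            )


class TestDoubleRing:
    def test_concentric_and_outer_taller(self):
        spec = DoubleRingSpec()
        col = build_double_ring(spec)
        inner_r = spec.inner.diameter / 2.0
        outer_r = spec.outer.diameter / 2.0
        inner_zmax = 0.0
        outer_zmax = 0.0
        for s in extrusion_segments(col):
            r = math.hypot(s.end.x, s.end.y)
            if abs(r - inner_r) < 1e-6:
                inner_zmax = max(inner_zmax, s.end.z)
            elif abs(r - outer_r) < 1e-6:
                outer_zmax = max(outer_zmax, s.end.z)
            else:  # pragma: no cover
                pytest.fail(f"extrusion at unexpected radius {r}")
        assert outer_zmax > inner_zmax

    def test_paths_radially_separated_in_plan_view(self):
        spec = DoubleRingSpec()
        gap = (spec.outer.diameter - spec.inner.diameter) / 2.0
        assert gap > 0
        for s in extrusion_segments(build_double_ring(spec)):
            r = math.hypot(s.end.x, s.end.y)
            assert r <= spec.inner.diameter / 2 + 1e-6 or r >= spec.outer.diameter / 2 - 1e-6

    def test_invalid_ordering_rejected(self):
        with pytest.raises(StructureError):
            DoubleRingSpec(
                inner=RingSpec(diameter=10, height=2), outer=RingSpec(diameter=8, height=4)
            )


class TestSorterGrid:
    def test_single_layer(self):
        segs = extrusion_segments(build_sorter_grid(GridSpec()))
        assert len({round(s.end.z, 9) for s in segs}) == 1

    def test_default_grid_encloses_38_cells(self):
        assert count_enclosed_cells(build_sorter_grid(GridSpec())) == 38

    def test_nominal_cell_area_is_pitch_squared(self):
        from shapely.geometry import LineString
        from shapely.ops import polygonize, unary_union

        segs = extrusion_segments(build_sorter_grid(GridSpec(pitch=1.0)))
        lines = [LineString([(s.start.x, s.start.y), (s.end.x, s.end.y)]) for s in segs]
        for face in polygonize(unary_union(lines)):
            assert face.area == pytest.approx(1.0, abs=1e-9)

    def test_pitch_below_nozzle_rejected(self):
        with pytest.raises(StructureError):
            build_sorter_grid(GridSpec(pitch=0.3))


class TestCountEnclosedCells:
    def _collection_from_polylines(self, polylines):
        b = ToolpathBuilder(PrintSettings())
        for pts in polylines:
            b.extrude_polyline(pts)
        return b.collection

    def test_one_closed_square(self):
        c = self._collection_from_polylines([square_polyline(0, 0, 1, 0.12)])
        assert count_enclosed_cells(c) == 1

    def test_two_disjoint_squares(self):
        c = self._collection_from_polylines(
            [square_polyline(0, 0, 1, 0.12), square_polyline(3, 0, 1, 0.12)]
        )
        assert count_enclosed_cells(c) == 2

    def test_non_planar_rejected(self):
        c = self._collection_from_polylines(
            [square_polyline(0, 0, 1, 0.12), square_polyline(3, 0, 1, 0.24)]
        )
        with pytest.raises(StructureError):
            count_enclosed_cells(c)

    def test_agrees_with_raster_flood_fill_on_random_lattices(self):
        """Bounded-face counting matches an independent raster flood-fill
        oracle on randomized sub-lattices (including interior holes)."""
        rng = random.Random(42)
        for _ in range(12):
            cols, rows = rng.randint(2, 5), rng.randint(2, 5)
            cells = [
                (c, r)
                for c in range(cols)
                for r in range(rows)
                if rng.random() < 0.7
            ]
            if not cells:
                continue
            polylines = [
                square_polyline(float(c), float(r), 1.0, 0.12) for c, r in cells
            ]
            col = self._collection_from_polylines(polylines)
            expected = raster_enclosed_regions(extrusion_segments(col))
            assert count_enclosed_cells(col) == expected

    def test_sorter_grid_agrees_with_raster_oracle(self):
        grid = build_sorter_grid(GridSpec())
        assert raster_enclosed_regions(extrusion_segments(grid)) == 38
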