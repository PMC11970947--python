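"""Geometry construction, fiber packing and rasterization checks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tumorperf import geometry as g
from tumorperf.fixtures import load_default_fiber_layout


class TestVesselGeometry:
    def test_default_depression_bounding_box(self):
        geo = g.build_vessel_geometry(g.VesselGeometryConfig())
        cx = geo.vessel.depression_center_x
        x0, x1, y0, y1 = geo.extent
        assert y0 == pytest.approx(-2.6)
        # fluid at the deepest point of the 5.2-um-wide depression
        assert geo.is_fluid(cx, -2.55)
        assert not geo.is_fluid(cx, -2.65)
        assert geo.is_fluid(cx - 2.59, -0.01)
        assert not geo.is_fluid(cx - 2.61, -0.01)

    def test_zero_depth_degenerates_to_straight_channel(self):
        cfg = g.VesselGeometryConfig(depression_depth=0.0)
        geo = g.build_vessel_geometry(cfg)
        assert geo.extent[2] == 0.0
        assert not geo.is_fluid(20.0, -0.1)

    def test_narrow_depression_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_vessel_geometry(
                g.VesselGeometryConfig(depression_diameter=4.0))

    def test_shallow_depression_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_vessel_geometry(
                g.VesselGeometryConfig(depression_depth=2.0))

    def test_depression_deeper_than_vessel_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_vessel_geometry(
                g.VesselGeometryConfig(vessel_height=2.0, depression_depth=2.6))

    def test_semicircular_arc_not_tangent_continuous(self):
        geo = g.build_vessel_geometry(g.VesselGeometryConfig())
        assert geo.tangent_continuous is False


class TestTumorGeometry:
    @pytest.mark.parametrize("model,d", [(1, 0.1), (2, 0.3), (3, 0.5)])
    def test_fenestra_diameter_per_model(self, model, d):
        cfg = g.TumorGeometryConfig(fenestra_diameter=d)
        geo = g.build_tumor_geometry(cfg)
        cx, top = cfg.center_x, cfg.tumor_height
        assert geo.in_fenestra(cx, top + 0.15)
        assert bool(geo.in_fenestra(cx + d / 2 + 0.02, top + 0.15)) is False

    def test_fenestra_must_be_smaller_than_depression(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_tumor_geometry(g.TumorGeometryConfig(fenestra_diameter=6.0))

    def test_fiber_overlapping_fenestra_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_tumor_geometry(g.TumorGeometryConfig(
                fiber_circles=((3.0, 5.9, 0.5),)))

    def test_fiber_outside_domain_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.build_tumor_geometry(g.TumorGeometryConfig(
                fiber_circles=((7.5, 3.0, 0.5),)))


class TestPackingFraction:
    def test_no_fibers_is_zero(self):
        geo = g.build_tumor_geometry(g.TumorGeometryConfig())
        assert g.packing_fraction(geo) == 0.0

    def test_single_circle_closed_form(self):
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            tumor_width=4.0, tumor_height=4.0,
            fiber_circles=((2.0, 2.0, 1.0),)))
        assert g.packing_fraction(geo) == pytest.approx(
            math.pi / 16.0, rel=1e-12)

    def test_clipped_circle_contributes_partial_area(self):
        # circle centred on the boundary: exactly half inside
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            tumor_width=4.0, tumor_height=4.0,
            fiber_circles=((0.0, 2.0, 0.5),)))
        assert g.packing_fraction(geo) == pytest.approx(
            math.pi * 0.25 / 2 / 16.0, rel=1e-3)

    def test_default_layout_hits_reference_density(self):
        circles = load_default_fiber_layout()
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            fiber_circles=tuple(circles)))
        assert g.packing_fraction(geo) == pytest.approx(0.27, abs=0.01)

    def test_default_layout_fits_default_domain(self):
        cfg = g.TumorGeometryConfig(
            fiber_circles=tuple(load_default_fiber_layout()))
        cfg.validate()  # no overlap with fenestra, all inside

    def test_translation_invariance_without_clipping(self):
        base = ((2.0, 2.0, 0.6), (4.2, 4.5, 0.7))
        shifted = tuple((x + 0.37, y - 0.21, r) for x, y, r in base)
        pf = [g.packing_fraction(g.build_tumor_geometry(
            g.TumorGeometryConfig(fiber_circles=c))) for c in (base, shifted)]
        assert pf[0] == pytest.approx(pf[1], rel=1e-12)

    def test_vessel_geometry_has_no_tumor_region(self):
        geo = g.build_vessel_geometry(g.VesselGeometryConfig())
        with pytest.raises(g.GeometryConfigError):
            g.packing_fraction(geo)


class TestPlaceFibers:
    def test_zero_target_empty(self):
        assert g.place_fibers(8.0, 8.0, 0.0) == []

    @pytest.mark.parametrize("target", [0.27, 0.30])
    def test_target_reached_without_overlap(self, target):
        circles = g.place_fibers(8.0, 8.0, target, rng_seed=0, min_gap=0.2)
        area = sum(math.pi * r * r for (_, _, r) in circles)
        assert area / 64.0 == pytest.approx(target, abs=0.01)
        # brute-force pairwise separation check
        for i, (x1, y1, r1) in enumerate(circles):
            for (x2, y2, r2) in circles[i + 1:]:
                assert math.hypot(x1 - x2, y1 - y2) >= r1 + r2 + 0.2 - 1e-9

    def test_deterministic_for_fixed_seed(self):
        a = g.place_fibers(8.0, 8.0, 0.27, rng_seed=7)
        b = g.place_fibers(8.0, 8.0, 0.27, rng_seed=7)
        assert a == b

    def test_unreachable_target_reports_achieved_fraction(self):
        with pytest.raises(g.GeometryConfigError, match="achieved"):
            g.place_fibers(8.0, 8.0, 0.55, rng_seed=0, max_attempts=200)

    def test_target_beyond_packing_bound_rejected(self):
        with pytest.raises(g.GeometryConfigError):
            g.place_fibers(8.0, 8.0, 0.95)


class TestRasterize:
    def test_unresolved_fenestra_rejected_with_advice(self):
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            fenestra_diameter=0.1))
        with pytest.raises(g.GeometryConfigError, match="cell_size"):
            g.rasterize(geo, 0.05)

    def test_plain_channel_interior_is_all_fluid(self):
        geo = g.build_vessel_geometry(g.VesselGeometryConfig(
            depression_depth=0.0))
        m = g.rasterize(geo, 0.5)
        interior = m.cell_class[1:-1, 1:-1]
        assert np.all(interior == g.CellClass.FLUID)

    def test_circle_area_converges_first_order(self):
        cfg = g.TumorGeometryConfig(tumor_width=4.0, tumor_height=4.0,
                                    fiber_circles=((2.0, 2.0, 1.0),))
        geo = g.build_tumor_geometry(cfg)
        errs = []
        for h in (0.08, 0.04, 0.02):
            m = g.rasterize(geo, h)
            errs.append(abs(m.solid_area() - math.pi) / math.pi)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.02

    def test_inlet_outlet_on_boundary_and_connected(self):
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            fiber_circles=tuple(load_default_fiber_layout())))
        m = g.rasterize(geo, 0.125)
        m.validate()  # raises on any violated mask invariant
        border = np.zeros_like(m.cell_class, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        io_cells = ((m.cell_class == g.CellClass.PRESSURE_INLET)
                    | (m.cell_class == g.CellClass.PRESSURE_OUTLET))
        assert np.all(border[io_cells])

    @pytest.mark.parametrize("model,d,h", [(1, 0.1, 0.025), (2, 0.3, 0.075),
                                           (3, 0.5, 0.125)])
    def test_flood_fill_connects_fenestra_to_outlet(self, model, d, h):
        geo = g.build_tumor_geometry(g.TumorGeometryConfig(
            fenestra_diameter=d,
            fiber_circles=tuple(load_default_fiber_layout())))
        m = g.rasterize(geo, h)  # validate() runs inside rasterize
        from scipy import ndimage
        openc = m.is_open() | (m.cell_class == g.CellClass.PRESSURE_INLET) \
            | (m.cell_class == g.CellClass.PRESSURE_OUTLET)
        labels, _ = ndimage.label(openc)
        lab_in = set(labels[m.cell_class == g.CellClass.PRESSURE_INLET]) - {0}
        lab_out = set(labels[m.cell_class == g.CellClass.PRESSURE_OUTLET]) - {0}
        assert lab_in == lab_out and len(lab_in) == 1
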