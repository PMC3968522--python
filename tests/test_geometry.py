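"""Exact construction of the lobule, square-variant and slab domains."""

import math

import numpy as np
import pytest

from lobuleflow.geometry import (
    BoundaryTag,
    GeometryError,
    SurfaceKind,
    VesselKind,
    build_hexagonal_lobule,
    build_square_lobule,
    build_surface_slab,
)
from lobuleflow.parameters import PhysiologicalParameters


@pytest.fixture
def params():
    return PhysiologicalParameters()


class TestHexagon:
    def test_portal_tracts_at_vertices_spaced_L_lob(self, params):
        geo = build_hexagonal_lobule(params)
        pts = [c for c in geo.cell.circles if c.kind is VesselKind.PT]
        assert len(pts) == 6
        centers = np.array([c.center for c in pts])
        # adjacent vertices of a regular hexagon with circumradius L are L apart
        d = np.hypot(*(centers - np.roll(centers, 1, axis=0)).T)
        assert np.allclose(d, params.L_lob, rtol=1e-12)
        assert np.allclose(np.hypot(*centers.T), params.L_lob, rtol=1e-12)

    def test_closed_form_areas(self, params):
        geo = build_hexagonal_lobule(params)
        L = params.L_lob
        assert geo.outline_area == pytest.approx(1.5 * math.sqrt(3) * L**2,
                                                 rel=1e-12)
        # six 120-degree PT wedges = two full disks, plus the CV disk
        r_pt, r_cv = params.D_PT / 2, params.D_CV / 2
        assert geo.vessel_area == pytest.approx(
            2 * math.pi * r_pt**2 + math.pi * r_cv**2, rel=1e-12)

    def test_septum_tags_on_all_edges(self, params):
        geo = build_hexagonal_lobule(params)
        assert all(t is BoundaryTag.SEPTUM for t in geo.cell.edge_tags)

    def test_overlapping_vessels_rejected(self, params):
        with pytest.raises((GeometryError, ValueError)):
            build_hexagonal_lobule(params.with_(D_PT=params.L_lob * 1.01))


class TestSquareVariant:
    def test_cross_section_and_vessel_areas_preserved_exactly(self, params):
        hexa = build_hexagonal_lobule(params)
        sq = build_square_lobule(params)
        assert sq.outline_area == pytest.approx(hexa.outline_area, rel=1e-12)
        assert sq.vessel_area == pytest.approx(hexa.vessel_area, rel=1e-12)
        assert sq.domain_area == pytest.approx(hexa.domain_area, rel=1e-12)

    def test_side_and_scaled_pt_radius(self, params):
        sq = build_square_lobule(params)
        s = math.sqrt(1.5 * math.sqrt(3)) * params.L_lob
        v = np.asarray(sq.cell.vertices)
        assert np.ptp(v[:, 0]) == pytest.approx(s, rel=1e-12)
        pt = [c for c in sq.cell.circles if c.kind is VesselKind.PT]
        assert len(pt) == 4
        assert pt[0].radius == pytest.approx(math.sqrt(2) * params.D_PT / 2,
                                             rel=1e-12)
        cv = [c for c in sq.cell.circles if c.kind is VesselKind.CV]
        assert cv[0].radius == params.D_CV / 2  # unchanged: one full disk each


class TestSlab:
    def test_surface_offsets_from_vessel_rows(self, params):
        slab = build_surface_slab(params, SurfaceKind.GLISSON_PERITONEAL, 4)
        L = params.L_lob
        pts = [c for cell in slab.cells for c in cell.circles
               if c.kind is VesselKind.PT]
        cvs = [c for cell in slab.cells for c in cell.circles
               if c.kind is VesselKind.CV]
        # surface is at y = 0
        assert min(c.center[1] for c in pts) == pytest.approx(L / 4)
        assert min(c.center[1] for c in cvs) == pytest.approx(3 * L / 4)

    def test_outermost_cell_area_equals_interior_cell_area(self, params):
        slab = build_surface_slab(params, SurfaceKind.BARE_AREA, 5)
        areas = [c.polygon_area() for c in slab.cells]
        # half-strip cells: pentagon and interior cells all carry half a lobule
        assert areas[0] == pytest.approx(areas[1], rel=1e-12)
        assert areas[1] == pytest.approx(areas[2], rel=1e-12)
        assert areas[0] == pytest.approx(
            0.75 * math.sqrt(3) * params.L_lob**2, rel=1e-12)
        # terminating half-cell is half of that
        assert areas[-1] == pytest.approx(areas[0] / 2, rel=1e-12)

    def test_edge_length_is_half_lattice_period(self, params):
        slab = build_surface_slab(params, SurfaceKind.GLISSON_PERITONEAL, 4)
        assert slab.L_edge == pytest.approx(math.sqrt(3) / 2 * params.L_lob)

    def test_surface_tag_only_on_outermost_cell(self, params):
        slab = build_surface_slab(params, SurfaceKind.GLISSON_PERITONEAL, 4)
        assert BoundaryTag.SURFACE in slab.cells[0].edge_tags
        for cell in slab.cells[1:]:
            assert BoundaryTag.SURFACE not in cell.edge_tags

    def test_cut_through_vessel_rejected(self, params):
        # a portal tract of radius >= L/4 would be cut by the surface
        with pytest.raises(GeometryError):
            build_surface_slab(params.with_(D_PT=0.6 * params.L_lob),
                               SurfaceKind.GLISSON_PERITONEAL, 4)

    def test_too_few_rows_rejected(self, params):
        with pytest.raises(GeometryError):
            build_surface_slab(params, SurfaceKind.BARE_AREA, 1)

    def test_shared_septum_endpoints_are_bitwise_identical(self, params):
        slab = build_surface_slab(params, SurfaceKind.GLISSON_PERITONEAL, 4)
        for lower, upper in zip(slab.cells[:-1], slab.cells[1:]):
            # the bottom septum endpoints of the upper cell must reuse the
            # lower cell's coordinates exactly (enables node merging)
            assert set(upper.vertices[:2]) <= set(lower.vertices)
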