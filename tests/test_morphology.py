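"""Geometry construction, elliptical trajectories, discretization, areas."""

import math

import numpy as np
import pytest

from rgcstim import morphology as M


class TestEllipticalPath:
    def test_vertex_conditions(self):
        spec = M.TrajectorySpec(35.0, 15.0, 120.0)
        pts = M.elliptical_axon_path(spec, 101)
        np.testing.assert_allclose(pts[0], [0, 0, -35.0], atol=1e-9)
        np.testing.assert_allclose(pts[-1], [120.0, 0, -15.0], atol=1e-9)
        # vertical extent 20 um (soma 35 below surface, 20 below the NFL)
        assert pts[:, 2].max() - pts[:, 2].min() == pytest.approx(20.0)

    def test_tangents_vertical_then_horizontal(self):
        pts = M.elliptical_axon_path(M.TrajectorySpec(35, 15, 100), 2001)
        d0 = pts[1] - pts[0]
        d1 = pts[-1] - pts[-2]
        assert abs(d0[0]) < 0.15 * abs(d0[2])     # near-vertical at the soma
        assert abs(d1[2]) < 0.15 * abs(d1[0])     # near-horizontal at the NFL

    def test_arc_length_bounds_and_monotone_in_reach(self):
        spec = M.TrajectorySpec(35, 15, 60)
        pts = M.elliptical_axon_path(spec, 500)
        arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert arc >= chord
        arcs = []
        for reach in (30.0, 60.0, 120.0, 240.0):
            p = M.elliptical_axon_path(M.TrajectorySpec(35, 15, reach), 500)
            arcs.append(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
        assert np.all(np.diff(arcs) > 0)

    @pytest.mark.parametrize("soma_depth, nfl_depth, reach", [
        (15.0, 15.0, 100.0), (10.0, 15.0, 100.0), (35.0, -1.0, 100.0),
        (35.0, 15.0, 0.0), (35.0, 15.0, -5.0),
    ])
    def test_invalid_specs_rejected(self, soma_depth, nfl_depth, reach):
        with pytest.raises(ValueError):
            M.TrajectorySpec(soma_depth, nfl_depth, reach)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            M.elliptical_axon_path(M.TrajectorySpec(), 1)


class TestBuildRgc:
    def test_region_path_lengths(self):
        m = M.build_rgc()
        for region, expected in [("soma", 20.0), ("hillock", 40.0),
                                 ("socb", 40.0), ("narrow", 75.0), ("axon", 3000.0)]:
            assert m.length[m.region == region].sum() == pytest.approx(expected)
        total = m.length[m.is_axial].sum()
        assert total == pytest.approx(3175.0)

    def test_optimized_compartment_counts(self):
        m = M.build_rgc()   # optimized per-region section lengths
        counts = {r: int((m.region == r).sum()) for r in M.AXIAL_REGIONS}
        assert counts == {"soma": 5, "hillock": 8, "socb": 8,
                          "narrow": 15, "axon": 600}

    def test_axon_count_at_5um(self):
        m = M.build_rgc(per_region_dx={"axon": 5.0})
        assert (m.region == "axon").sum() == 600

    def test_no_dendrite_mode(self):
        m = M.build_rgc(dendrite_mode="none")
        assert (m.region == "dendrite").sum() == 0

    def test_socb_taper_monotone(self):
        m = M.build_rgc()
        socb = m.region_index("socb")
        d = m.diameter[socb]
        assert np.all(np.diff(d) < 0)
        assert m.d_prox[socb[0]] == pytest.approx(3.0)
        assert m.d_dist[socb[-1]] == pytest.approx(0.8)

    def test_invariants_hold_for_all_variants(self):
        for mode in ("none", "equivalent-cylinder", "branched-from-file"):
            m = M.build_rgc(dendrite_mode=mode, seed=3)
            m.validate()   # raises on violation

    def test_missing_region_rejected(self):
        secs = [s for s in M.default_sections() if s.region != "narrow"]
        with pytest.raises(ValueError, match="narrow"):
            M.build_rgc(sections=secs)

    def test_curve_shorter_than_regions_spills_horizontally(self):
        # a very steep ellipse: most of the narrow region continues at NFL depth
        m = M.build_rgc(trajectory=M.TrajectorySpec(35, 15, 25))
        narrow = m.region_index("narrow")
        assert np.all(np.abs(m.z[narrow] + 15.0) < 1.0)

    def test_equivalent_cylinder_layout(self):
        specs = M.equivalent_cylinder_dendrite()
        assert [s.length for s in specs] == [10.0, 810.0, 810.0]
        m = M.build_rgc(dendrite_mode="equivalent-cylinder")
        dend = m.region_index("dendrite")
        horiz = dend[np.abs(m.x[dend]) > 1e-9]
        assert m.length[horiz].sum() == pytest.approx(1620.0)
        assert m.x[horiz].max() > 800 and m.x[horiz].min() < -800
        # vertical stub attaches within a soma radius of the soma axis
        vert = dend[np.abs(m.x[dend]) <= 1e-9]
        soma_bottom = m.z[m.region_index("soma")].min() - 2.0
        assert np.all(m.z[vert] < soma_bottom + 12.0)


class TestDiscretizeAndArea:
    def test_discretize_idempotent(self):
        m = M.build_rgc()
        again = M.discretize(m, M.DEFAULT_DX)
        np.testing.assert_allclose(again.length, m.length)
        np.testing.assert_allclose(again.arc, m.arc)
        np.testing.assert_allclose(again.diameter, m.diameter)

    def test_dx_larger_than_section_gives_single_compartment(self):
        m = M.build_rgc(per_region_dx={r: 1e6 for r in M.REGIONS})
        assert all((m.region == r).sum() == 1 for r in M.AXIAL_REGIONS)

    def test_soma_area_closed_form(self):
        m = M.build_rgc()
        assert M.surface_area(m, "soma") == pytest.approx(math.pi * 20 * 20, rel=1e-9)

    def test_somatodendritic_area_matches_printed_value(self):
        m = M.build_rgc(dendrite_mode="equivalent-cylinder")
        area = M.surface_area(m, ("soma", "dendrite"))
        assert area == pytest.approx(math.pi * (20 * 20 + 4 * 10 + 2 * 1620), rel=1e-9)
        assert area == pytest.approx(11560.0, abs=2.0)

    def test_area_additive_and_discretization_invariant(self):
        m = M.build_rgc()
        total = M.surface_area(m)
        by_region = sum(M.surface_area(m, r) for r in M.AXIAL_REGIONS)
        assert total == pytest.approx(by_region, rel=1e-12)
        fine = M.discretize(m, {r: 1.0 for r in M.REGIONS})
        assert M.surface_area(fine) == pytest.approx(total, rel=1e-9)

    def test_empty_selection_is_zero(self):
        m = M.build_rgc()
        assert M.surface_area(m, ()) == 0.0

    def test_nonpositive_dx_rejected(self):
        m = M.build_rgc()
        with pytest.raises(ValueError):
            M.discretize(m, {"axon": 0.0})
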