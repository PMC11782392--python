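"""Synthetic anatomy and triangulation."""

import numpy as np
import pytest
from dataclasses import replace

from aaaprobe.errors import GeometryError
from aaaprobe.geometry import (GeometrySpec, make_geometry,
                               patient_archetypes, triangulate)
from aaaprobe.geometry import _triangle_angles


def polygon_area(pts):
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(pts, closed=True):
    p = np.vstack([pts, pts[:1]]) if closed else pts
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


class TestMakeGeometry:
    def test_circular_lumen_circumference(self):
        spec = GeometrySpec(d_max=50.0, lumen_ellipticity=1.0, n_wall=256)
        g = make_geometry(spec)
        L = polyline_length(g.lumen_midsurface)
        assert L == pytest.approx(np.pi * 50.0, rel=1e-3)

    def test_determinism_same_seed(self):
        spec = GeometrySpec(perturb_amplitude=0.02, seed=42)
        g1, g2 = make_geometry(spec), make_geometry(spec)
        assert np.array_equal(g1.lumen_midsurface, g2.lumen_midsurface)
        assert np.array_equal(g1.abdomen_contour, g2.abdomen_contour)

    def test_different_seed_differs_when_perturbed(self):
        g1 = make_geometry(GeometrySpec(perturb_amplitude=0.02, seed=1))
        g2 = make_geometry(GeometrySpec(perturb_amplitude=0.02, seed=2))
        assert not np.array_equal(g1.lumen_midsurface, g2.lumen_midsurface)

    def test_abdomen_area_matches_ellipse(self):
        g = make_geometry(GeometrySpec(abdomen_semi_axes=(160.0, 110.0)))
        area = polygon_area(g.abdomen_contour)
        assert area == pytest.approx(np.pi * 160.0 * 110.0, rel=5e-3)

    def test_infeasible_specs_rejected(self):
        with pytest.raises(GeometryError):
            make_geometry(GeometrySpec(d_max=3.0, wall_thickness=2.0))
        with pytest.raises(GeometryError):
            make_geometry(GeometrySpec(aorta_depth=150.0, spine_gap=80.0))
        with pytest.raises(GeometryError):
            make_geometry(GeometrySpec(probe_width=400.0))

    def test_probe_segment_is_anterior_and_centered(self):
        g = make_geometry(GeometrySpec())
        assert np.all(g.probe_segment[:, 1] > 0)
        assert abs(g.probe_segment[:, 0].mean()) < 2.0
        assert np.ptp(g.probe_segment[:, 0]) <= 70.0


class TestArchetypes:
    def test_specs_valid_and_in_surveillance_range(self, archetypes):
        assert len(archetypes) == 3
        for spec in archetypes.values():
            spec.validate()
            assert 45.0 <= spec.d_max <= 55.0

    def test_mutually_distinct(self, archetypes):
        specs = list(archetypes.values())
        fields = ("d_max", "lumen_ellipticity", "spine_gap", "aorta_depth")
        for i in range(3):
            for j in range(i + 1, 3):
                n_diff = sum(getattr(specs[i], f) != getattr(specs[j], f)
                             for f in fields)
                assert n_diff >= 2

    def test_p3_has_strongest_spine_constraint(self, archetypes):
        gaps = {k: v.spine_gap for k, v in archetypes.items()}
        assert gaps["P3"] == min(gaps.values())


class TestTriangulate:
    def test_annulus_topology_and_tie_constraint(self, small_mesh):
        m = small_mesh
        edges = np.unique(np.sort(np.concatenate(
            [m.triangles[:, e] for e in ((0, 1), (1, 2), (2, 0))]), axis=1),
            axis=0)
        # Euler characteristic of a disk with two holes: V - E + F = -1
        assert m.n_nodes - len(edges) + len(m.triangles) == -1
        # every lumen node belongs to >= 1 wall segment and >= 1 triangle
        lumen = set(int(i) for i in m.node_sets["lumen"])
        in_seg = set(int(i) for i in m.wall_segments.ravel())
        in_tri = set(int(i) for i in m.triangles.ravel())
        assert lumen <= in_seg and lumen <= in_tri

    def test_positive_orientation_and_quality(self, small_mesh):
        m = small_mesh
        v1 = m.nodes[m.triangles[:, 1]] - m.nodes[m.triangles[:, 0]]
        v2 = m.nodes[m.triangles[:, 2]] - m.nodes[m.triangles[:, 0]]
        assert np.all(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0] > 0)
        assert np.rad2deg(
            _triangle_angles(m.nodes, m.triangles).min()) >= 20.0

    def test_wall_element_count_matches_spec(self, archetypes):
        for name, spec in archetypes.items():
            g = make_geometry(spec)
            # wall segments equal the configured lumen discretization,
            # within the cohort band 82 +/- 4
            assert abs(spec.n_wall - 82) <= 4
            assert len(g.lumen_midsurface) == spec.n_wall

    def test_node_sets_disjoint(self, p1_mesh):
        spine = set(int(i) for i in p1_mesh.node_sets["spine"])
        probe = set(int(i) for i in p1_mesh.node_sets["probe"])
        wall = set(int(i) for i in p1_mesh.node_sets["wall"])
        assert not spine & probe
        assert not spine & wall
        assert not probe & wall

    def test_halving_mesh_size_grows_element_count(self):
        spec = GeometrySpec()
        m1 = triangulate(make_geometry(spec))
        fine = replace(spec, mesh_size=spec.mesh_size / 2,
                       n_wall=2 * spec.n_wall)
        m2 = triangulate(make_geometry(fine))
        ratio = len(m2.triangles) / len(m1.triangles)
        assert 3.0 <= ratio <= 5.0

    def test_determinism(self, small_spec):
        m1 = triangulate(make_geometry(small_spec))
        m2 = triangulate(make_geometry(small_spec))
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.triangles, m2.triangles)


class TestGeometryJson:
    def test_round_trip(self, tmp_path):
        from aaaprobe.geometry import geometry_from_json, geometry_to_json

        g = make_geometry(GeometrySpec(perturb_amplitude=0.01, seed=5))
        p = tmp_path / "geom.json"
        geometry_to_json(g, p)
        g2 = geometry_from_json(p)
        assert np.allclose(g.lumen_midsurface, g2.lumen_midsurface)
        assert g2.provenance == g.provenance
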