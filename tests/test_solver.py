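"""Nonlinear FE solver: closed-form oracles, equilibrium, invariances."""

import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from aaaprobe.constitutive import (HGOWall, LinearWall, TissueParams,
                                   neo_hookean_stress)
from aaaprobe.errors import ConvergenceError, GeometryError
from aaaprobe.geometry import rect_mesh, ring_mesh
from aaaprobe.solver import (ModelAssembly, SolverControls,
                             extract_wall_fields, pressure_load_residual,
                             reaction_forces, solve_static)


def ring_assembly(wall, pressure, n=82, radius=25.0):
    mesh = ring_mesh(radius, wall.thickness, n)
    pins = np.array([0, 1, 2 * (n // 2) + 1])   # kill rigid modes only
    return ModelAssembly(mesh, wall=wall, lumen_pressure=pressure,
                         extra_fixed_dofs=pins)


def patch_assembly(tissue, traction, nx=4, ny=4, order=2):
    """Rectangle with roller left/bottom edges, follower traction on the
    right edge (negative pressure = tension)."""
    mesh = rect_mesh(10.0, 10.0, nx, ny)
    mesh.probe_edges = mesh.node_sets["right_edges"]
    asm = ModelAssembly(mesh, tissue=tissue, probe_pressure=-traction,
                        element_order=order,
                        clamped_nodes=np.empty(0, dtype=int))
    fixed = [2 * mesh.node_sets["left"], 2 * mesh.node_sets["bottom"] + 1]
    if order == 2:
        fixed += [2 * asm.midside_nodes_of(mesh.node_sets["left"]),
                  2 * asm.midside_nodes_of(mesh.node_sets["bottom"]) + 1]
    return ModelAssembly(mesh, tissue=tissue, probe_pressure=-traction,
                         element_order=order,
                         clamped_nodes=np.empty(0, dtype=int),
                         extra_fixed_dofs=np.concatenate(fixed))


class TestZeroLoad:
    def test_zero_loads_zero_displacement_one_iteration(self, soft_tissue):
        asm = patch_assembly(soft_tissue, 0.0)
        st = solve_static(asm, (0.0, 0.0))
        assert np.all(st.displacements == 0.0)
        assert st.newton_iterations == 1


class TestHomogeneousPatchOracle:
    def test_matches_plane_strain_closed_form(self, soft_tissue):
        """Uniform follower traction on a homogeneous patch reproduces the
        homogeneous plane-strain solution to machine precision."""
        p = 3.0
        asm = patch_assembly(soft_tissue, p)
        st = solve_static(asm, (1.0, 0.0))

        def eqs(v):
            sig = neo_hookean_stress(np.diag(v), soft_tissue, tangent=False)
            return [sig[0, 0] - p, sig[1, 1]]

        l1, l2 = fsolve(eqs, [1.1, 0.95], xtol=1e-13)
        ux = st.displacements[asm.mesh.node_sets["right"], 0]
        uy = st.displacements[asm.mesh.node_sets["top"], 1]
        assert np.ptp(ux) < 1e-10
        assert 1.0 + ux.mean() / 10.0 == pytest.approx(l1, rel=1e-10)
        assert 1.0 + uy.mean() / 10.0 == pytest.approx(l2, rel=1e-10)


class TestRingInflationOracle:
    """Isolated wall ring under internal pressure vs the scalar membrane
    equilibrium P·r(λ) = σ(λ)·t(λ), solved independently by bisection."""

    @pytest.mark.parametrize("wall_cls", [HGOWall, LinearWall])
    @pytest.mark.parametrize("pressure", [5.0, 10.0, 15.0])
    def test_matches_laplace_oracle(self, wall_cls, pressure):
        wall = wall_cls()
        asm = ring_assembly(wall, pressure)
        st = solve_static(asm, (0.0, 1.0))
        lam_oracle = brentq(
            lambda lam: pressure * 25.0 * lam - wall.tension(lam)[0],
            1.0 + 1e-6, 1.45, xtol=1e-12)
        assert np.ptp(st.wall_lambda) < 1e-10      # uniform inflation
        assert st.wall_lambda.mean() == pytest.approx(lam_oracle, rel=0.01)

    def test_uniform_ring_strain_field(self):
        wall = HGOWall()
        asm = ring_assembly(wall, 10.0)
        ref = solve_static(asm, (0.0, 0.0))
        st = solve_static(asm, (0.0, 1.0))
        sigma, eps = extract_wall_fields(asm, st, ref)
        lam = st.wall_lambda.mean()
        assert np.allclose(eps, lam - 1.0, atol=1e-8)
        assert np.allclose(sigma, wall.stress(lam)[0], rtol=1e-8)
        ref2 = st
        _, eps0 = extract_wall_fields(asm, st, ref2)
        assert np.all(eps0 == 0.0)


class TestPressureLoads:
    def test_closed_contour_self_equilibrated(self):
        mesh = ring_mesh(25.0, 2.0, 82)
        f, _ = pressure_load_residual(mesh.wall_segments, 10.0, mesh.nodes)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_open_segment_resultant_pressure_times_length(self):
        # straight 70 mm segment at 30 kPa -> 2.1 N/mm per unit depth
        coords = np.column_stack([np.linspace(-35.0, 35.0, 15),
                                  np.zeros(15)])
        edges = np.column_stack([np.arange(14), np.arange(1, 15)])
        f, _ = pressure_load_residual(edges, 30.0, coords)
        resultant = f.sum(axis=0)
        assert resultant[0] == pytest.approx(0.0, abs=1e-10)
        assert abs(resultant[1]) == pytest.approx(30.0 * 70.0, rel=1e-12)

    def test_linear_in_magnitude(self):
        mesh = ring_mesh(20.0, 2.0, 40)
        f1, _ = pressure_load_residual(mesh.wall_segments, 4.0, mesh.nodes)
        f2, _ = pressure_load_residual(mesh.wall_segments, 8.0, mesh.nodes)
        assert np.allclose(f2, 2.0 * f1, atol=1e-12)

    def test_degenerate_edge_signals(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(GeometryError):
            pressure_load_residual(np.array([[0, 1]]), 5.0, coords)


class TestEquilibriumAndInvariance:
    def test_reactions_balance_applied_loads(self, soft_tissue):
        """Sum of clamped reactions equals the integral of the applied
        probe pressure on the deformed boundary."""
        mesh = rect_mesh(10.0, 10.0, 4, 4)
        mesh.probe_edges = mesh.node_sets["right_edges"]
        asm = ModelAssembly(mesh, tissue=soft_tissue, probe_pressure=2.0,
                            clamped_nodes=mesh.node_sets["left"],
                            probe_taper=0.0)
        st = solve_static(asm, (1.0, 0.0))
        R = reaction_forces(asm, st)
        xy = asm.X_full + st.u_full.reshape(-1, 2)
        f, _ = pressure_load_residual(asm.probe_edges, -2.0, xy)
        total = f.sum(axis=0)
        assert np.abs(R.sum(axis=0) + total).max() < 1e-6 * np.abs(
            total).max()

    def test_objectivity_under_rotated_reference(self, soft_tissue):
        """Rigidly rotating the reference geometry rotates the solution."""
        th = 0.6
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mesh1 = rect_mesh(10.0, 10.0, 3, 3)
        mesh1.probe_edges = mesh1.node_sets["right_edges"]
        asm1 = ModelAssembly(mesh1, tissue=soft_tissue, probe_pressure=1.5,
                             clamped_nodes=mesh1.node_sets["left"],
                             probe_taper=0.0)
        st1 = solve_static(asm1, (1.0, 0.0))
        mesh2 = rect_mesh(10.0, 10.0, 3, 3)
        mesh2.nodes = mesh2.nodes @ Q.T
        mesh2.probe_edges = mesh2.node_sets["right_edges"]
        asm2 = ModelAssembly(mesh2, tissue=soft_tissue, probe_pressure=1.5,
                             clamped_nodes=mesh2.node_sets["left"],
                             probe_taper=0.0)
        st2 = solve_static(asm2, (1.0, 0.0))
        assert np.allclose(st2.displacements, st1.displacements @ Q.T,
                           atol=1e-8)

    def test_mirror_symmetric_problem_gives_mirror_solution(self):
        """A symmetric ring under uniform pressure: x-mirror nodes displace
        as mirror images."""
        wall = HGOWall()
        n = 40
        asm = ring_assembly(wall, 8.0, n=n)
        st = solve_static(asm, (0.0, 1.0))
        u = st.displacements
        # the pins lie on the x-axis, so the problem is mirror-symmetric
        # about y -> -y: node k at angle 2πk/n mirrors to node n-k
        for k in range(1, n // 2):
            assert u[k, 0] == pytest.approx(u[n - k, 0], abs=1e-8)
            assert u[k, 1] == pytest.approx(-u[n - k, 1], abs=1e-8)


class TestStepping:
    def test_divergence_signals_convergence_error(self):
        # absurd load on a soft patch: must raise, not hang
        tissue = TissueParams(mu=0.5)
        asm = patch_assembly(tissue, 500.0)
        with pytest.raises(ConvergenceError):
            solve_static(asm, (1.0, 0.0),
                         SolverControls(n_steps=1, max_newton=8,
                                        max_halvings=2))

    def test_determinism(self, soft_tissue):
        asm = patch_assembly(soft_tissue, 2.0)
        u1 = solve_static(asm, (1.0, 0.0)).displacements
        u2 = solve_static(asm, (1.0, 0.0)).displacements
        assert np.array_equal(u1, u2)
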