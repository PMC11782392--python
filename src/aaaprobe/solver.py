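"""Geometrically nonlinear static FE solver for the tissue–wall system.

Total Lagrangian formulation.  The tissue region is discretized with plane
strain triangles — linear (1-point) or quadratic (3-point Gauss, the
default) — carrying the nearly incompressible neo-Hookean law.  The aneurysm
wall is a chain of 2-node geometrically nonlinear membrane segments along the
lumen mid-surface carrying the hoop tension ``N(λ)`` of the active wall law;
wall nodes are tissue nodes, so the tie constraint holds by construction.

Quadratic tissue elements are generated internally by inserting midside
nodes on the linear triangulation; they relieve the volumetric locking that
plain linear triangles exhibit near the incompressible limit.

Loads are follower pressures: the lumen (blood) pressure acts on the
deformed wall segments, the probe pressure on the deformed probe footprint
of the abdomen contour.  Both contribute a (nonsymmetric) load-stiffness
term.  Equilibrium is found with Newton–Raphson under linear load stepping
with automatic step halving (at most 4 halvings) on divergence; the sparse
tangent is factorized with a direct solver, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .constitutive import HGOWall, LinearWall, TissueParams, neo_hookean_pk1
from .errors import ConvergenceError, ElementInversionError
from .geometry import Mesh

__all__ = [
    "SolverControls",
    "ModelAssembly",
    "SolveState",
    "solve_static",
    "pressure_load_residual",
    "extract_wall_fields",
    "reaction_forces",
]

# quadratic triangle: corners 0,1,2 then midsides (0,1), (1,2), (2,0)
_T6_EDGES = ((0, 1), (1, 2), (2, 0))
# degree-2 Gauss rule on the reference triangle (area coords)
_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.array([1 / 6, 1 / 6, 1 / 6])


def _t6_shape_gradients(xi, eta):
    """d N_a / d(xi, eta) of the 6-node triangle at one reference point."""
    lam = np.array([1.0 - xi - eta, xi, eta])
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    dN = np.zeros((6, 2))
    for a in range(3):
        dN[a] = (4.0 * lam[a] - 1.0) * dlam[a]
    for m, (a, b) in enumerate(_T6_EDGES):
        dN[3 + m] = 4.0 * (lam[a] * dlam[b] + lam[b] * dlam[a])
    return dN


@dataclass(frozen=True)
class SolverControls:
    """Newton/stepping tolerances.  Residual scale is the external force
    norm of the increment; convergence at relative 1e-8 or absolute
    1e-10 N/mm = 1e-7 kPa·mm (internal force unit, per unit depth)."""

    rtol: float = 1.0e-8
    atol: float = 1.0e-7
    max_newton: int = 30
    n_steps: int = 5
    max_halvings: int = 4


@dataclass
class SolveState:
    """Converged (or last attempted) equilibrium state."""

    displacements: np.ndarray            # (n_mesh_nodes, 2) mm
    converged: bool
    residual_norm: float
    newton_iterations: int
    wall_lambda: np.ndarray              # per wall segment
    wall_sigma: np.ndarray               # kPa
    load_factors_applied: tuple[float, float]   # (probe, lumen)
    u_full: np.ndarray = field(repr=False, default=None)  # internal dofs


class ModelAssembly:
    """Mesh + materials + boundary conditions + load magnitudes.

    ``lumen_pressure`` and ``probe_pressure`` are the *target* magnitudes
    (kPa); :func:`solve_static` scales them by load factors.  The reference
    (stress-free) configuration may differ from ``mesh.nodes`` — that is how
    the zero-pressure geometry enters.
    """

    def __init__(self, mesh: Mesh,
                 wall: HGOWall | LinearWall | None = None,
                 tissue: TissueParams | None = None,
                 reference_coords: np.ndarray | None = None,
                 lumen_pressure: float = 0.0,
                 probe_pressure: float = 0.0,
                 element_order: int = 2,
                 clamped_nodes: np.ndarray | None = None,
                 extra_fixed_dofs: np.ndarray | None = None,
                 out_of_plane_length: float | None = 20.0,
                 probe_taper: float = 0.3):
        if element_order not in (1, 2):
            raise ValueError("element_order must be 1 or 2")
        if wall is None and len(mesh.wall_segments):
            raise ValueError("mesh has wall segments but no wall material")
        self.mesh = mesh
        self.wall = wall
        self.tissue = tissue
        self.element_order = element_order if len(mesh.triangles) else 1
        self.lumen_pressure = float(lumen_pressure)
        self.probe_pressure = float(probe_pressure)
        X = mesh.nodes if reference_coords is None else reference_coords
        self.reference_mesh_coords = np.asarray(X, dtype=float).copy()
        if clamped_nodes is None:
            clamped_nodes = mesh.node_sets.get("spine",
                                               np.empty(0, dtype=int))
        self.clamped_nodes = np.asarray(clamped_nodes, dtype=int)
        self.extra_fixed_dofs = (np.empty(0, dtype=int)
                                 if extra_fixed_dofs is None
                                 else np.asarray(extra_fixed_dofs, dtype=int))
        #: Out-of-plane shear-lag correction.  The cross section is a slice
        #: of a 3D body; probe-induced fields decay out of plane over the
        #: probe's 20 mm footprint, which a plane-strain model cannot see.
        #: An elastic foundation k = μ(π/2ℓ)² acting on the displacement
        #: *deviation from* ``foundation_anchor`` restores that decay.  The
        #: anchor is set by the protocol to the no-probe diastolic state, so
        #: z-uniform blood-pressure inflation is unaffected.  ``None``
        #: recovers pure plane strain.
        self.out_of_plane_length = out_of_plane_length
        #: Fraction of the probe half-footprint over which the applied
        #: pressure rolls off (cosine^2) to zero.  A curved-array transducer
        #: face does not apply a sharp pressure step at its rim; the taper
        #: also removes the crease-like strain singularity a step load
        #: induces on a soft half-space.  0 → uniform pressure.
        self.probe_taper = float(probe_taper)
        self.foundation_anchor: np.ndarray | None = None
        self.foundation_force: np.ndarray | None = None
        self._build()

    def freeze_foundation(self, u_full) -> None:
        """Replace the foundation spring by its current (dead) force.

        Used between the probe and systole stages: the probe-induced,
        out-of-plane-localized deformation keeps its support, while the
        z-uniform cyclic inflation no longer feels the foundation
        stiffness."""
        if self.foundation_anchor is None or not self.out_of_plane_length:
            return
        kdof = self._foundation_stiffness() * np.repeat(self._node_area, 2)
        self.foundation_force = kdof * (u_full - self.foundation_anchor)
        self.foundation_anchor = None

    def _foundation_stiffness(self) -> float:
        """Foundation modulus k = μ (π/2ℓ_z)² (kPa/mm² per unit depth).

        Modal stiffness of a half-cosine out-of-plane decay profile of
        length ℓ_z: the dominant z-mode of a field forced over the probe's
        out-of-plane footprint."""
        return self.tissue.mu * (np.pi / (2.0 * self.out_of_plane_length)
                                 ) ** 2

    # -- discretization ----------------------------------------------------
    def _build(self):
        mesh = self.mesh
        n_corner = mesh.n_nodes
        tris = mesh.triangles
        if self.element_order == 2 and len(tris):
            edges = np.sort(np.concatenate(
                [tris[:, e] for e in _T6_EDGES]), axis=1)
            uniq, inv = np.unique(edges, axis=0, return_inverse=True)
            self._edge_nodes = uniq                     # (n_edge, 2)
            mid_ids = n_corner + inv.reshape(3, -1).T   # (n_el, 3)
            self.conn = np.hstack([tris, mid_ids])
            self.n_total = n_corner + len(uniq)
        else:
            self._edge_nodes = np.empty((0, 2), dtype=int)
            self.conn = tris
            self.n_total = n_corner
        self.n_corner = n_corner
        self.X_full = self._full_coords(self.reference_mesh_coords)

        # quadrature / reference gradients (constant Jacobian: straight sides)
        if len(tris):
            Xc = self.reference_mesh_coords
            J = np.stack([Xc[tris[:, 1]] - Xc[tris[:, 0]],
                          Xc[tris[:, 2]] - Xc[tris[:, 0]]], axis=2)  # (e,2,a)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(detJ <= 0):
                raise ElementInversionError("negative reference Jacobian",
                                            int(np.argmax(detJ <= 0)))
            Jinv = np.empty_like(J)
            Jinv[:, 0, 0] = J[:, 1, 1]
            Jinv[:, 0, 1] = -J[:, 0, 1]
            Jinv[:, 1, 0] = -J[:, 1, 0]
            Jinv[:, 1, 1] = J[:, 0, 0]
            Jinv /= detJ[:, None, None]
            if self.element_order == 2:
                dN = np.stack([_t6_shape_gradients(x, e) for x, e in _QP])
                # G[e,q,a,J] = dN[q,a,al] Jinv[e,al,J]
                self.G = np.einsum("qac,ecJ->eqaJ", dN, Jinv)
                self.w = detJ[:, None] * _QW[None, :]
            else:
                dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
                self.G = np.einsum("ac,ecJ->eaJ", dN, Jinv)[:, None]
                self.w = detJ[:, None] * 0.5
            n_en = self.conn.shape[1]
            dofs = (2 * self.conn[:, :, None]
                    + np.arange(2)[None, None, :]).reshape(len(tris), -1)
            self._tis_rows = np.repeat(dofs, 2 * n_en, axis=1).ravel()
            self._tis_cols = np.tile(dofs, (1, 2 * n_en)).ravel()

        # lumped nodal areas for the out-of-plane foundation
        self._node_area = np.zeros(self.n_total)
        if len(tris):
            area_el = self.w.sum(axis=1)
            share = np.repeat(area_el[:, None] / self.conn.shape[1],
                              self.conn.shape[1], axis=1)
            np.add.at(self._node_area, self.conn, share)

        # wall segments
        segs = mesh.wall_segments
        if len(segs):
            Xr = self.reference_mesh_coords
            self.wall_L0 = np.linalg.norm(
                Xr[segs[:, 1]] - Xr[segs[:, 0]], axis=1)
            sd = (2 * segs[:, :, None]
                  + np.arange(2)[None, None, :]).reshape(len(segs), -1)
            self._wall_rows = np.repeat(sd, 4, axis=1).ravel()
            self._wall_cols = np.tile(sd, (1, 4)).ravel()

        # pressure edge sets; probe edges become 3-node quadratic edges
        # (end, midside, end) for T6 so the follower load stays consistent
        self.lumen_edges = segs.copy()
        pe = mesh.probe_edges
        if self.element_order == 2 and len(pe):
            mid = self._midside_lookup(pe)
            self.probe_edges = np.column_stack([pe[:, 0], mid, pe[:, 1]])
        else:
            self.probe_edges = pe.copy()
        # probe-rim pressure taper weights from reference edge midpoints
        self._probe_weights = np.ones(len(self.probe_edges))
        spec = getattr(mesh, "provenance", None)
        if spec is not None and self.probe_taper > 0 and len(self.probe_edges):
            half = spec.probe_width / 2.0
            x0 = (1.0 - self.probe_taper) * half
            xm = self.X_full[self.probe_edges].mean(axis=1)[:, 0]
            s = np.clip((np.abs(xm) - x0) / max(half - x0, 1e-9), 0.0, 1.0)
            self._probe_weights = np.cos(0.5 * np.pi * s) ** 2

        self._pressure_idx = {}
        for name, e in (("lumen", self.lumen_edges),
                        ("probe", self.probe_edges)):
            if len(e):
                k = 2 * e.shape[1]
                ed = (2 * e[:, :, None]
                      + np.arange(2)[None, None, :]).reshape(len(e), -1)
                self._pressure_idx[name] = (
                    np.repeat(ed, k, axis=1).ravel(),
                    np.tile(ed, (1, k)).ravel())

        # fixed dofs: clamped corner nodes + midsides of clamped edges
        clamped = set(int(i) for i in self.clamped_nodes)
        fixed_nodes = list(clamped)
        for k, (a, b) in enumerate(self._edge_nodes):
            if int(a) in clamped and int(b) in clamped:
                fixed_nodes.append(n_corner + k)
        fixed = np.concatenate([
            (2 * np.asarray(fixed_nodes, dtype=int)[:, None]
             + np.arange(2)).ravel() if fixed_nodes else np.empty(0, int),
            self.extra_fixed_dofs]).astype(int)
        mask = np.ones(2 * self.n_total, dtype=bool)
        mask[fixed] = False
        self.free = np.flatnonzero(mask)
        self.fixed = np.flatnonzero(~mask)

    def midside_nodes_of(self, node_set) -> np.ndarray:
        """Internal midside node ids of edges with both ends in ``node_set``
        (empty for linear elements).  Useful for constraining whole edges."""
        s = set(int(i) for i in node_set)
        return np.array([self.n_corner + k
                         for k, (a, b) in enumerate(self._edge_nodes)
                         if int(a) in s and int(b) in s], dtype=int)

    def _midside_lookup(self, pairs):
        key = {tuple(e): self.n_corner + k
               for k, e in enumerate(map(tuple, self._edge_nodes))}
        out = np.empty(len(pairs), dtype=int)
        for i, (a, b) in enumerate(np.sort(pairs, axis=1)):
            out[i] = key[(int(a), int(b))]
        return out

    def _full_coords(self, mesh_coords):
        if len(self._edge_nodes):
            mids = 0.5 * (mesh_coords[self._edge_nodes[:, 0]]
                          + mesh_coords[self._edge_nodes[:, 1]])
            return np.vstack([mesh_coords, mids])
        return mesh_coords.copy()

    # -- residual / tangent ------------------------------------------------
    def assemble(self, u_full, probe_factor, lumen_factor):
        """Internal minus external force and consistent tangent.

        Returns ``(residual, K, f_ext_norm)`` on the full dof vector.
        """
        x = self.X_full + u_full.reshape(-1, 2)
        ndof = 2 * self.n_total
        f_int = np.zeros(ndof)
        f_ext = np.zeros(ndof)
        data, rows, cols = [], [], []

        if len(self.mesh.triangles):
            conn = self.conn
            n_el, n_en = conn.shape
            xe = x[conn]                                   # (e, a, i)
            F = np.einsum("eai,eqaJ->eqiJ", xe, self.G)
            Fb = F.reshape(-1, 2, 2)
            P, A = neo_hookean_pk1(Fb, self.tissue)
            nq = self.G.shape[1]
            P = P.reshape(n_el, nq, 2, 2)
            A = A.reshape(n_el, nq, 2, 2, 2, 2)
            fe = np.einsum("eq,eqiJ,eqaJ->eai", self.w, P, self.G)
            np.add.at(f_int, (2 * conn[:, :, None]
                              + np.arange(2)).ravel(), fe.ravel())
            ke = np.einsum("eq,eqaJ,eqiJkL,eqbL->eaibk",
                           self.w, self.G, A, self.G, optimize=True)
            data.append(ke.reshape(n_el, -1).ravel())
            rows.append(self._tis_rows)
            cols.append(self._tis_cols)

        segs = self.mesh.wall_segments
        if len(segs):
            x1, x2 = x[segs[:, 0]], x[segs[:, 1]]
            vec = x2 - x1
            l = np.linalg.norm(vec, axis=1)
            if np.any(l <= 0):
                raise ElementInversionError("wall segment collapsed",
                                            int(np.argmax(l <= 0)))
            d = vec / l[:, None]
            lam = l / self.wall_L0
            N, dN = self.wall.tension(lam)
            fseg = N[:, None] * d
            np.add.at(f_int, 2 * segs[:, 0], -fseg[:, 0])
            np.add.at(f_int, 2 * segs[:, 0] + 1, -fseg[:, 1])
            np.add.at(f_int, 2 * segs[:, 1], fseg[:, 0])
            np.add.at(f_int, 2 * segs[:, 1] + 1, fseg[:, 1])
            dd = np.einsum("si,sj->sij", d, d)
            eye = np.eye(2)[None]
            kmat = (dN / self.wall_L0)[:, None, None] * dd \
                + (N / l)[:, None, None] * (eye - dd)
            kblock = np.empty((len(segs), 4, 4))
            kblock[:, :2, :2] = kmat
            kblock[:, 2:, 2:] = kmat
            kblock[:, :2, 2:] = -kmat
            kblock[:, 2:, :2] = -kmat
            data.append(kblock.ravel())
            rows.append(self._wall_rows)
            cols.append(self._wall_cols)
            self._last_wall = (lam, l)

        # follower pressures: lumen outward (+), probe inward (-)
        for name, edges, mag in (
                ("lumen", self.lumen_edges,
                 lumen_factor * self.lumen_pressure),
                ("probe", self.probe_edges,
                 -probe_factor * self.probe_pressure
                 * self._probe_weights)):
            if not len(edges) or np.all(mag == 0.0):
                continue
            fe, kblock = _pressure_blocks(edges, x, mag)
            np.add.at(f_ext, (2 * edges[:, :, None]
                              + np.arange(2)).ravel(), fe.ravel())
            r, c = self._pressure_idx[name]
            data.append(-kblock.ravel())   # K_total = K_int - dF_ext/dx
            rows.append(r)
            cols.append(c)

        # out-of-plane shear-lag foundation (probe-induced deviations only)
        if (self.foundation_anchor is not None
                and self.out_of_plane_length
                and self.tissue is not None and len(self.mesh.triangles)):
            kdof = self._foundation_stiffness() * np.repeat(
                self._node_area, 2)
            f_int += kdof * (u_full - self.foundation_anchor)
            idx = np.arange(ndof)
            data.append(kdof)
            rows.append(idx)
            cols.append(idx)
        elif self.foundation_force is not None:
            f_int += self.foundation_force

        K = sp.coo_matrix(
            (np.concatenate(data),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof, ndof)).tocsr()
        return f_int - f_ext, K, float(np.linalg.norm(f_ext))


# consistent load coefficient matrices: f_a = p * S @ (C x)_a with
# S = 90-deg rotation; exact (and exactly linear in x) for straight or
# curved edges, so the load stiffness is constant.
_S_ROT = np.array([[0.0, 1.0], [-1.0, 0.0]])
_C_LIN = np.array([[-0.5, 0.5], [-0.5, 0.5]])
_C_QUAD = np.array([[-1 / 2, 2 / 3, -1 / 6],
                    [-2 / 3, 0.0, 2 / 3],
                    [1 / 6, -2 / 3, 1 / 2]])


def _pressure_blocks(edges, x, p):
    """Follower-pressure nodal forces and load-stiffness blocks.

    ``edges`` has 2 (linear) or 3 (quadratic, end–mid–end) node columns;
    orientation first → last node.  The pressure resultant ``p * rot(t)``
    with ``t = x_last − x_first`` points along the outward normal of a CCW
    contour.  Returns per-edge nodal forces (n, n_en, 2) and the constant
    d(f_ext)/d(x_nodes) blocks (n, 2 n_en, 2 n_en).
    """
    from .errors import GeometryError

    n_en = edges.shape[1]
    C = _C_LIN if n_en == 2 else _C_QUAD
    xe = x[edges]                                  # (n, n_en, 2)
    t = xe[:, -1] - xe[:, 0]
    if np.any(np.einsum("ij,ij->i", t, t) == 0.0):
        raise GeometryError("degenerate (zero-length) pressure edge")
    p_edge = np.broadcast_to(np.asarray(p, dtype=float), len(edges))
    fe = p_edge[:, None, None] * np.einsum("ab,ij,nbj->nai", C, _S_ROT, xe)
    kblock = (p_edge[:, None, None]
              * np.kron(C, _S_ROT)[None])          # (n, 2n_en, 2n_en)
    return fe, kblock


def pressure_load_residual(edges, magnitude, coords):
    """Nodal follower-pressure forces on an oriented polyline (public).

    Returns ``(forces, load_stiffness_blocks)``: forces shaped like
    ``coords`` and the per-edge 4×4 configuration-derivative blocks.
    On a closed CCW contour the force resultant vanishes; on an open
    segment its magnitude is ``|magnitude| × current length``.
    """
    edges = np.asarray(edges, dtype=int)
    coords = np.asarray(coords, dtype=float)
    fe, kblock = _pressure_blocks(edges, coords, magnitude)
    f = np.zeros_like(coords)
    for a in range(edges.shape[1]):
        np.add.at(f, edges[:, a], fe[:, a])
    return f, kblock


def solve_static(assembly: ModelAssembly,
                 targets: tuple[float, float] = (1.0, 1.0),
                 controls: SolverControls | None = None,
                 state0: SolveState | None = None) -> SolveState:
    """Drive the assembly to the target load factors ``(probe, lumen)``.

    Ramps linearly from the factors of ``state0`` (or from zero) in
    ``controls.n_steps`` increments; on Newton divergence or element
    inversion the current increment is halved (up to ``max_halvings``
    times).  Deterministic for fixed inputs.
    """
    controls = controls or SolverControls()
    ndof = 2 * assembly.n_total
    if state0 is not None and state0.u_full is not None:
        u = state0.u_full.copy()
        f_start = np.asarray(state0.load_factors_applied, dtype=float)
    else:
        u = np.zeros(ndof)
        f_start = np.zeros(2)
    f_target = np.asarray(targets, dtype=float)
    free = assembly.free

    total_iters = 0
    n_halved = 0
    current = f_start.copy()
    remaining = 1.0          # fraction of (f_target - f_start) still to apply
    frac_step = 1.0 / max(1, controls.n_steps)
    if np.allclose(f_start, f_target):
        remaining = 0.0

    last_res = np.inf
    delta_prev = None
    step_prev = None
    while remaining > 1e-12:
        step = min(frac_step, remaining)
        trial_target = f_target - (remaining - step) * (f_target - f_start)
        ok = False
        # secant predictor from the previous increment, then plain start
        predictors = ([step / step_prev]
                      if delta_prev is not None else []) + [0.0]
        for scale in predictors:
            u_trial = u + scale * delta_prev if scale else u.copy()
            ok, iters, last_res = _newton(assembly, u_trial, trial_target,
                                          controls)
            total_iters += iters
            if ok:
                break
        if ok:
            # reuse the predictor only while convergence is comfortable
            delta_prev = (u_trial - u) if iters <= 10 else None
            step_prev = step
            u = u_trial
            current = trial_target
            remaining -= step
            continue
        n_halved += 1
        if n_halved > controls.max_halvings:
            raise ConvergenceError(
                f"no convergence after {controls.max_halvings} step "
                f"halvings (last residual {last_res:.3e}, step {step:.3g})",
                residual=last_res, step=step)
        frac_step *= 0.5
        delta_prev = None

    # final residual bookkeeping (also covers the zero-load case)
    R, _, fext_norm = assembly.assemble(u, *f_target)
    res = float(np.linalg.norm(R[free]))
    segs = assembly.mesh.wall_segments
    if len(segs):
        lam = getattr(assembly, "_last_wall", (np.ones(len(segs)),))[0]
        sig = assembly.wall.stress(lam)[0]
    else:
        lam = np.empty(0)
        sig = np.empty(0)
    return SolveState(
        displacements=u.reshape(-1, 2)[:assembly.mesh.n_nodes].copy(),
        converged=True, residual_norm=res,
        newton_iterations=max(total_iters, 1),
        wall_lambda=np.asarray(lam, dtype=float).copy(),
        wall_sigma=np.asarray(sig, dtype=float).copy(),
        load_factors_applied=(float(f_target[0]), float(f_target[1])),
        u_full=u)


def _newton(assembly, u, factors, controls):
    """Newton iteration in place on ``u``; returns (converged, iters, res).

    A trial step that inverts an element or produces a non-finite residual
    is backtracked (halved, up to 5 times) before the increment is declared
    divergent.
    """
    free = assembly.free
    res = np.inf

    from .errors import StretchRangeError

    def try_assemble(vec):
        # inversion/overflow in a trial state is recoverable: backtrack
        try:
            R, K, fn = assembly.assemble(vec, *factors)
        except (ElementInversionError, StretchRangeError):
            return None
        if not np.isfinite(R[free]).all():
            return None
        return R, K, fn

    out = try_assemble(u)
    if out is None:
        return False, 1, np.inf
    for it in range(1, controls.max_newton + 1):
        R, K, fext_norm = out
        res = float(np.linalg.norm(R[free]))
        tol = max(controls.rtol * fext_norm, controls.atol)
        if res < tol:
            return True, it, res
        Kff = K[free][:, free]
        du = spsolve(Kff.tocsc(), -R[free])
        if not np.all(np.isfinite(du)):
            return False, it, res
        scale = 1.0
        for _ in range(6):
            u_try = u.copy()
            u_try[free] += scale * du
            out = try_assemble(u_try)
            if out is not None:
                u[:] = u_try
                break
            scale *= 0.5
        else:
            return False, it, res
    return False, controls.max_newton, res


def extract_wall_fields(assembly: ModelAssembly, state: SolveState,
                        reference: SolveState):
    """Per-wall-element circumferential stress and cyclic strain.

    ``sigma_circ`` is evaluated from the wall law at the stretch of
    ``state``; ``eps_circ`` is the engineering strain of each segment
    between the two converged states (e.g. diastole → systole at constant
    probe pressure).
    """
    segs = assembly.mesh.wall_segments
    if len(state.displacements) != len(reference.displacements):
        raise ValueError("states come from different assemblies")
    Xr = assembly.reference_mesh_coords

    def seg_lengths(st):
        xy = Xr + st.displacements
        return np.linalg.norm(xy[segs[:, 1]] - xy[segs[:, 0]], axis=1)

    l_state = seg_lengths(state)
    l_ref = seg_lengths(reference)
    eps = (l_state - l_ref) / l_ref
    lam = l_state / assembly.wall_L0
    sigma = assembly.wall.stress(lam)[0]
    return np.asarray(sigma, dtype=float), eps


def reaction_forces(assembly: ModelAssembly, state: SolveState):
    """Nodal reactions at fixed dofs (kPa·mm per unit depth)."""
    R, _, _ = assembly.assemble(state.u_full,
                                *state.load_factors_applied)
    out = np.zeros(2 * assembly.n_total)
    out[assembly.fixed] = R[assembly.fixed]
    return out.reshape(-1, 2)
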