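"""Synthetic cross-sectional anatomy and triangulation.

The model plane is the maximum-diameter cross section of an abdominal aortic
aneurysm: the clinical ultrasound scanning plane.  Real cohorts are imaged by
CT and segmented by hand; here the anatomy is generated parametrically —
an elliptical abdomen outline, an elliptical aneurysm lumen (wall
mid-surface), a circular spine cut posterior to the aneurysm, and a probe
footprint on the anterior abdominal surface.  Three "patient archetypes"
emulate the qualitative variation of a small surveillance cohort (sac
roundness, spine proximity, aorta depth); their parameter values are our own
invention and are labeled as such.

Coordinates: origin at the lumen centroid of the reference geometry,
+y anterior (toward the probe), −y posterior (toward the spine); mm.

Triangulation is a force-equilibration (distmesh-style) mesher: seeded
points relax under edge spring forces inside a signed-distance description of
the tissue domain, retriangulated with Delaunay.  Element size is graded from
``mesh_size`` at the aneurysm wall up to ``far_size_factor``× that value at
the abdomen outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LinearRing, LineString, Polygon

from .errors import GeometryError, MeshQualityError

__all__ = [
    "GeometrySpec",
    "CrossSectionGeometry",
    "Mesh",
    "make_geometry",
    "patient_archetypes",
    "triangulate",
    "geometry_to_json",
    "geometry_from_json",
    "ring_mesh",
    "rect_mesh",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric description of one scanning-plane anatomy.  Lengths in mm."""

    d_max: float = 50.0               # AP lumen (mid-surface) diameter
    wall_thickness: float = 2.0       # aneurysm wall thickness
    lumen_ellipticity: float = 1.0    # lateral/AP lumen axis ratio
    abdomen_semi_axes: tuple[float, float] = (160.0, 110.0)  # (lateral, AP)
    aorta_depth: float = 45.0         # anterior abdomen surface -> anterior wall
    spine_gap: float = 8.0            # posterior wall -> spine arc
    spine_radius: float = 15.0
    probe_width: float = 70.0         # in-plane probe footprint
    mesh_size: float = 2.0            # target element edge at the wall
    n_wall: int = 82                  # wall membrane elements around the lumen
    n_contour: int = 256              # vertices for dense analytic contours
    perturb_amplitude: float = 0.0    # relative radial contour perturbation
    seed: int = 0

    def validate(self) -> None:
        a_lat, a_ap = self.abdomen_semi_axes
        if not self.d_max > 2.0 * self.wall_thickness:
            raise GeometryError(
                f"violated d_max > 2*wall_thickness: {self.d_max} <= "
                f"{2 * self.wall_thickness}")
        if not (self.aorta_depth + self.d_max + self.spine_gap
                + 2.0 * self.spine_radius < 2.0 * a_ap):
            raise GeometryError(
                "violated: aorta_depth + d_max + spine_gap + spine diameter "
                "must fit within the abdomen AP extent")
        if not self.probe_width <= 2.0 * a_lat:
            raise GeometryError(
                "violated probe_width <= abdomen lateral extent")
        if self.lumen_ellipticity * self.d_max / 2.0 >= a_lat:
            raise GeometryError("violated: lumen wider than the abdomen")
        if self.lumen_ellipticity <= 0 or self.spine_gap <= 0:
            raise GeometryError("lumen_ellipticity and spine_gap must be > 0")
        if self.n_wall < 8 or self.mesh_size <= 0:
            raise GeometryError("n_wall >= 8 and mesh_size > 0 required")


@dataclass(frozen=True)
class CrossSectionGeometry:
    """Analytic contours of one anatomy, as closed/open polylines (mm)."""

    abdomen_contour: np.ndarray       # (n, 2) closed (last != first)
    spine_arc: np.ndarray             # (m, 2) closed circle polyline
    lumen_midsurface: np.ndarray      # (n_wall, 2) closed
    probe_segment: np.ndarray         # (k, 2) sub-polyline of the abdomen
    provenance: GeometrySpec

    def validate(self) -> None:
        abd = Polygon(self.abdomen_contour)
        lum = Polygon(self.lumen_midsurface)
        spn = Polygon(self.spine_arc)
        for name, poly in (("abdomen", abd), ("lumen", lum), ("spine", spn)):
            if not poly.is_valid or not LinearRing(
                    np.asarray(poly.exterior.coords)[:-1]).is_simple:
                raise GeometryError(f"{name} contour is not simple")
        if not abd.contains(lum):
            raise GeometryError("lumen not strictly inside abdomen")
        if not abd.contains(spn):
            raise GeometryError("spine not inside abdomen")
        if lum.intersects(spn):
            raise GeometryError("lumen and spine contours overlap")


@dataclass
class Mesh:
    """Discretized tissue + wall model.

    Tissue: 3-node triangles (positively oriented).  Wall: 2-node membrane
    segments along the lumen mid-surface, sharing node ids with the tissue
    triangulation — the tie constraint is built in.  ``node_sets`` carries
    {"spine" (clamped), "probe" (loaded), "lumen"/"wall" (pressure-loaded,
    identical)}.  ``probe_edges`` are consecutive abdomen-boundary node pairs,
    oriented CCW like the contour.
    """

    nodes: np.ndarray                    # (N, 2) mm
    triangles: np.ndarray                # (M, 3) int
    wall_segments: np.ndarray            # (W, 2) int, CCW around the lumen
    wall_thickness: float
    node_sets: dict[str, np.ndarray]
    probe_edges: np.ndarray              # (P, 2) int
    provenance: GeometrySpec | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Analytic geometry
# ---------------------------------------------------------------------------

def _ellipse(center, a, b, n, phase=0.0):
    t = phase + np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t),
                            center[1] + b * np.sin(t)])


def _perturb(contour, center, amplitude, rng, modes=(2, 3, 4)):
    """Smooth seeded radial perturbation (low-order Fourier modes)."""
    if amplitude == 0.0:
        return contour
    rel = contour - center
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    factor = np.ones(len(contour))
    for k in modes:
        a, b = rng.normal(size=2)
        factor += amplitude * (a * np.cos(k * phi) + b * np.sin(k * phi))
    return center + rel * factor[:, None]


def make_geometry(spec: GeometrySpec) -> CrossSectionGeometry:
    """Generate the analytic contours for one anatomy.

    The probe footprint is centered on the anterior abdomen point closest to
    the lumen (x = 0 by construction); the spine circle sits ``spine_gap``
    behind the posterior wall.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a_lat, a_ap = spec.abdomen_semi_axes
    b_ap = spec.d_max / 2.0
    b_lat = spec.lumen_ellipticity * b_ap
    abd_center = np.array([0.0, b_ap + spec.aorta_depth - a_ap])
    spine_center = np.array(
        [0.0, -b_ap - spec.spine_gap - spec.spine_radius])

    lumen = _ellipse((0.0, 0.0), b_lat, b_ap, spec.n_wall,
                     phase=np.pi / spec.n_wall)
    abdomen = _ellipse(abd_center, a_lat, a_ap, spec.n_contour)
    n_spine = max(24, int(2 * np.pi * spec.spine_radius / spec.mesh_size / 2))
    spine = _ellipse(spine_center, spec.spine_radius, spec.spine_radius,
                     n_spine)

    lumen = _perturb(lumen, np.zeros(2), spec.perturb_amplitude, rng)
    abdomen = _perturb(abdomen, abd_center, 0.5 * spec.perturb_amplitude, rng)

    half_w = spec.probe_width / 2.0
    on_probe = (np.abs(abdomen[:, 0]) <= half_w) & (abdomen[:, 1]
                                                    > abd_center[1])
    probe = abdomen[on_probe]
    probe = probe[np.argsort(probe[:, 0])]

    geom = CrossSectionGeometry(
        abdomen_contour=abdomen, spine_arc=spine, lumen_midsurface=lumen,
        probe_segment=probe, provenance=spec)
    geom.validate()
    return geom


#: Brachial blood pressures (P_dias, P_sys, mmHg) paired with each archetype,
#: matching a three-patient surveillance cohort.
ARCHETYPE_PRESSURES_MMHG = {"P1": (76.0, 138.0),
                            "P2": (90.0, 153.0),
                            "P3": (88.0, 144.0)}


def patient_archetypes() -> dict[str, GeometrySpec]:
    """Three synthetic patient archetypes for the scanning plane.

    P1 and P3 encode elongated aneurysm sacs (laterally elliptic cross
    sections), P2 a near-spherical sac (circular, largest diameter); P3 sits
    closest to the spine (strongest posterior constraint) and deepest below
    the abdominal surface.  All AP diameters lie in the clinically
    surveilled 45–55 mm band around the repair threshold.  The values are
    synthetic: they reproduce cohort-like variation, not any real patient.
    """
    return {
        "P1": GeometrySpec(d_max=50.0, lumen_ellipticity=1.08,
                           aorta_depth=45.0, spine_gap=8.0, n_wall=82),
        "P2": GeometrySpec(d_max=55.0, lumen_ellipticity=1.00,
                           aorta_depth=40.0, spine_gap=10.0, n_wall=86),
        "P3": GeometrySpec(d_max=46.0, lumen_ellipticity=1.16,
                           aorta_depth=50.0, spine_gap=4.0, n_wall=78),
    }


# ---------------------------------------------------------------------------
# Triangulation (distmesh-style force equilibration)
# ---------------------------------------------------------------------------

def _signed_distance(points, domain, boundary):
    d = shapely.distance(shapely.points(points), boundary)
    inside = shapely.contains_xy(domain, points[:, 0], points[:, 1])
    return np.where(inside, -d, d)


def _resample_closed(contour, sizes_at):
    """Resample a closed polyline with locally prescribed spacing."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    h = sizes_at(closed)
    h_seg = 0.5 * (h[:-1] + h[1:])
    units = np.concatenate([[0.0], np.cumsum(seg / h_seg)])
    n = max(8, int(round(units[-1])))
    target = np.linspace(0.0, units[-1], n, endpoint=False)
    s_new = np.interp(target, units, s)
    x = np.interp(s_new, s, closed[:, 0])
    y = np.interp(s_new, s, closed[:, 1])
    return np.column_stack([x, y])


def triangulate(geom: CrossSectionGeometry,
                mesh_size: float | None = None,
                far_size_factor: float = 7.0,
                max_iter: int = 100,
                min_angle_deg: float = 20.0) -> Mesh:
    """Triangulate the tissue domain (abdomen minus lumen minus spine cut).

    Lumen mid-surface vertices are fixed points, so wall membrane segments
    and tissue triangles share node ids along the interface.  Element size
    grows linearly with distance from the lumen, from ``mesh_size`` up to
    ``far_size_factor * mesh_size``.

    Raises :class:`MeshQualityError` if the relaxed mesh misses a wall edge
    or its minimum triangle angle falls below ``min_angle_deg``.
    """
    spec = geom.provenance
    h0 = float(mesh_size if mesh_size is not None else spec.mesh_size)
    h_max = far_size_factor * h0
    rng = np.random.default_rng(spec.seed + 1)

    domain = Polygon(geom.abdomen_contour,
                     holes=[geom.lumen_midsurface, geom.spine_arc])
    boundary = domain.boundary
    lumen_line = LinearRing(geom.lumen_midsurface)
    probe_line = LineString(geom.probe_segment)

    def sizefun(pts):
        gpts = shapely.points(pts)
        d_lum = shapely.distance(gpts, lumen_line)
        d_prb = shapely.distance(gpts, probe_line)
        h = np.minimum(h0 + 0.35 * d_lum, 2.5 * h0 + 0.35 * d_prb)
        return np.clip(h, h0, h_max)

    # fixed boundary points: lumen vertices exactly, abdomen and spine
    # resampled at the local target size
    lumen_pts = geom.lumen_midsurface
    abd_pts = _resample_closed(geom.abdomen_contour, sizefun)
    spine_pts = _resample_closed(geom.spine_arc, sizefun)
    fixed = np.vstack([lumen_pts, abd_pts, spine_pts])
    n_lumen, n_abd = len(lumen_pts), len(abd_pts)

    # seed interior points on a triangular lattice, thinned by the size
    # function (keep probability (h0/h)^2), then drop any too close to a
    # boundary
    xmin, ymin = geom.abdomen_contour.min(axis=0) - h0
    xmax, ymax = geom.abdomen_contour.max(axis=0) + h0
    xs = np.arange(xmin, xmax, h0)
    ys = np.arange(ymin, ymax, h0 * np.sqrt(3) / 2.0)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += h0 / 2.0
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    keep = rng.random(len(cand)) < (h0 / sizefun(cand)) ** 2
    cand = cand[keep]
    d = _signed_distance(cand, domain, boundary)
    cand = cand[d < -0.55 * sizefun(cand)]

    pts = np.vstack([fixed, cand])
    n_fixed = len(fixed)

    def delaunay_tris(p):
        tri = Delaunay(p)
        cent = p[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(domain, cent[:, 0], cent[:, 1])
        return tri.simplices[inside]

    tris = delaunay_tris(pts)
    last_pts = pts.copy()
    for _ in range(max_iter):
        if np.max(np.linalg.norm(pts - last_pts, axis=1)) > 0.1 * h0:
            tris = delaunay_tris(pts)
            last_pts = pts.copy()
        edges = np.unique(
            np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                    tris[:, [2, 0]]]), axis=1), axis=0)
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        L = np.linalg.norm(vec, axis=1)
        mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
        hbar = sizefun(mid)
        L0 = hbar * 1.2 * np.sqrt(np.sum(L ** 2) / np.sum(hbar ** 2))
        fmag = np.maximum(L0 - L, 0.0)
        fvec = (fmag / np.maximum(L, 1e-12))[:, None] * vec
        force = np.zeros_like(pts)
        np.add.at(force, edges[:, 0], -fvec)
        np.add.at(force, edges[:, 1], fvec)
        force[:n_fixed] = 0.0
        pts += 0.2 * force
        # project escaped movable points back to the boundary
        dmov = _signed_distance(pts[n_fixed:], domain, boundary)
        out = np.where(dmov > -0.2 * h0)[0] + n_fixed
        if len(out):
            eps = 1e-3 * h0
            px = _signed_distance(pts[out] + [eps, 0.0], domain, boundary)
            py = _signed_distance(pts[out] + [0.0, eps], domain, boundary)
            d_out = _signed_distance(pts[out], domain, boundary)
            grad = np.column_stack([(px - d_out), (py - d_out)]) / eps
            gn = np.maximum(np.linalg.norm(grad, axis=1), 1e-12)
            pts[out] -= ((d_out + 0.35 * h0) / gn ** 2)[:, None] * grad
        if np.max(np.linalg.norm(0.2 * force[n_fixed:], axis=1),
                  initial=0.0) < 5e-3 * h0:
            break

    tris = delaunay_tris(pts)
    # drop orphan movable points and renumber
    used = np.unique(tris)
    if not np.all(np.isin(np.arange(n_fixed), used)):
        raise MeshQualityError("a fixed boundary point lost all triangles")
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tris = remap[tris]

    # positive orientation
    v1 = pts[tris[:, 1]] - pts[tris[:, 0]]
    v2 = pts[tris[:, 2]] - pts[tris[:, 0]]
    flip = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0] < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    wall_ids = remap[np.arange(n_lumen)]
    wall_segments = np.column_stack([wall_ids, np.roll(wall_ids, -1)])
    edge_set = {tuple(sorted(e)) for t in ((0, 1), (1, 2), (2, 0))
                for e in tris[:, t]}
    for a, b in wall_segments:
        if (min(a, b), max(a, b)) not in edge_set:
            raise MeshQualityError(
                "wall segment not recovered by the triangulation; "
                "refine mesh_size")

    angles = _triangle_angles(pts, tris)
    if angles.min() < np.deg2rad(min_angle_deg):
        raise MeshQualityError(
            f"minimum triangle angle {np.rad2deg(angles.min()):.1f} deg "
            f"below {min_angle_deg} deg")

    abd_ids = remap[np.arange(n_lumen, n_lumen + n_abd)]
    spine_ids = remap[np.arange(n_lumen + n_abd, n_fixed)]
    half_w = spec.probe_width / 2.0
    abd_xy = pts[abd_ids]
    abd_cy = abd_xy[:, 1].mean()
    probe_mask = (np.abs(abd_xy[:, 0]) <= half_w) & (abd_xy[:, 1] > abd_cy)
    probe_ids = abd_ids[probe_mask]
    # consecutive CCW pairs along the abdomen ring restricted to the probe
    ring_next = {int(a): int(b)
                 for a, b in zip(abd_ids, np.roll(abd_ids, -1))}
    probe_set = set(int(i) for i in probe_ids)
    probe_edges = np.array([[a, ring_next[a]] for a in probe_set
                            if ring_next[a] in probe_set], dtype=int)

    mesh = Mesh(nodes=pts, triangles=tris, wall_segments=wall_segments,
                wall_thickness=spec.wall_thickness,
                node_sets={"lumen": wall_ids, "wall": wall_ids,
                           "spine": spine_ids, "probe": probe_ids,
                           "abdomen": abd_ids},
                probe_edges=probe_edges, provenance=spec)
    return mesh


def _triangle_angles(pts, tris):
    p = pts[tris]
    ang = np.empty((len(tris), 3))
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        ang[:, i] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return ang


# ---------------------------------------------------------------------------
# Geometry (de)serialization: JSON with contours as vertex lists
# ---------------------------------------------------------------------------

def geometry_to_json(geom: CrossSectionGeometry, path) -> None:
    import dataclasses
    import json
    from pathlib import Path

    payload = {
        "abdomen_contour": geom.abdomen_contour.tolist(),
        "spine_arc": geom.spine_arc.tolist(),
        "lumen_midsurface": geom.lumen_midsurface.tolist(),
        "probe_segment": geom.probe_segment.tolist(),
        "provenance": dataclasses.asdict(geom.provenance),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def geometry_from_json(path) -> CrossSectionGeometry:
    import json
    from pathlib import Path

    raw = json.loads(Path(path).read_text())
    prov = raw["provenance"]
    prov["abdomen_semi_axes"] = tuple(prov["abdomen_semi_axes"])
    geom = CrossSectionGeometry(
        abdomen_contour=np.asarray(raw["abdomen_contour"], dtype=float),
        spine_arc=np.asarray(raw["spine_arc"], dtype=float),
        lumen_midsurface=np.asarray(raw["lumen_midsurface"], dtype=float),
        probe_segment=np.asarray(raw["probe_segment"], dtype=float),
        provenance=GeometrySpec(**prov))
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# Structured test meshes
# ---------------------------------------------------------------------------

def ring_mesh(radius: float = 25.0, thickness: float = 2.0,
              n: int = 82) -> Mesh:
    """Isolated circular wall ring (no tissue): n membrane segments.

    Used for closed-form membrane-equilibrium checks; node 0 sits at
    (radius, 0) and segments run CCW.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    nodes = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
    ids = np.arange(n)
    segs = np.column_stack([ids, np.roll(ids, -1)])
    return Mesh(nodes=nodes, triangles=np.empty((0, 3), dtype=int),
                wall_segments=segs, wall_thickness=thickness,
                node_sets={"lumen": ids, "wall": ids,
                           "spine": np.empty(0, dtype=int),
                           "probe": np.empty(0, dtype=int)},
                probe_edges=np.empty((0, 2), dtype=int))


def rect_mesh(width: float = 10.0, height: float = 10.0,
              nx: int = 4, ny: int = 4) -> Mesh:
    """Structured right-triangle mesh of a rectangle (tissue only).

    Node sets: "left", "right", "bottom", "top" edge nodes; "spine" empty.
    Edge sets "right_edges"/"top_edges" (CCW outward) are stored in
    ``node_sets`` with an ``_edges`` suffix for traction tests.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            tris.append([a, b, c])
            tris.append([a, c, d])
    sets = {
        "left": np.array([nid(0, j) for j in range(ny + 1)]),
        "right": np.array([nid(nx, j) for j in range(ny + 1)]),
        "bottom": np.array([nid(i, 0) for i in range(nx + 1)]),
        "top": np.array([nid(i, ny) for i in range(nx + 1)]),
        "spine": np.empty(0, dtype=int),
        "probe": np.empty(0, dtype=int),
        # CCW boundary orientation: outward normals via (t_y, -t_x)
        "right_edges": np.array([[nid(nx, j), nid(nx, j + 1)]
                                 for j in range(ny)]),
        "top_edges": np.array([[nid(nx - i, ny), nid(nx - i - 1, ny)]
                               for i in range(nx)]),
    }
    return Mesh(nodes=nodes, triangles=np.array(tris, dtype=int),
                wall_segments=np.empty((0, 2), dtype=int),
                wall_thickness=0.0, node_sets=sets,
                probe_edges=np.empty((0, 2), dtype=int))
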