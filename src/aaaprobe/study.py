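"""Factorial simulation study: probe pressure × surrounding tissue × wall model.

The full design crosses 3 patient archetypes × 3 probe conditions
(LPP/MPP/FPP) × 3 surrounding-tissue shear moduli (5/10/20 kPa) × 2 wall
constitutive models (HGO / linearized orthotropic) = 54 runs.  Each run
performs the complete pipeline — mesh, zero-pressure recovery, staged
loading, in-silico measurement — and reports the measured diameters and
circumferences, the β stiffness indexes, and per-wall-element field
summaries (circumferential stress at diastole+probe; cyclic strain
diastole→systole at constant probe).  ELIs are computed per
(patient, wall model, tissue stiffness) from the LPP and FPP rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import HGOWall, LinearWall, TissueParams
from .errors import MeasurementError
from .geometry import (ARCHETYPE_PRESSURES_MMHG, GeometrySpec, make_geometry,
                       patient_archetypes, triangulate)
from .indexes import eli, stiffness
from .protocol import BloodPressure, ProbeCondition, run_protocol
from .solver import (ModelAssembly, SolverControls,
                     extract_wall_fields)
from .zero_pressure import compute_zero_pressure

log = logging.getLogger(__name__)

__all__ = ["StudyDesign", "FieldSummary", "run_study", "compare_conditions",
           "StudyResult"]


@dataclass(frozen=True)
class StudyDesign:
    """The factorial design; defaults reproduce the full 54-run study."""

    patients: tuple[str, ...] = ("P1", "P2", "P3")
    probe_levels: tuple[str, ...] = ("LPP", "MPP", "FPP")
    st_moduli: tuple[float, ...] = (5.0, 10.0, 20.0)     # kPa
    wall_models: tuple[str, ...] = ("hgo", "linear")

    @property
    def n_runs(self) -> int:
        return (len(self.patients) * len(self.probe_levels)
                * len(self.st_moduli) * len(self.wall_models))


@dataclass
class FieldSummary:
    """Quartile summary of per-wall-element fields in the cross section."""

    n_elements: int
    sigma_q1: float
    sigma_median: float
    sigma_q3: float
    sigma_min: float
    sigma_max: float
    eps_q1: float
    eps_median: float
    eps_q3: float

    @classmethod
    def from_fields(cls, sigma, eps) -> "FieldSummary":
        sq1, sme, sq3 = np.percentile(sigma, [25, 50, 75])
        eq1, eme, eq3 = np.percentile(eps, [25, 50, 75])
        return cls(n_elements=len(sigma), sigma_q1=float(sq1),
                   sigma_median=float(sme), sigma_q3=float(sq3),
                   sigma_min=float(np.min(sigma)),
                   sigma_max=float(np.max(sigma)),
                   eps_q1=float(eq1), eps_median=float(eme),
                   eps_q3=float(eq3))


@dataclass
class StudyResult:
    runs: pd.DataFrame          # one row per simulation
    eli: pd.DataFrame           # one row per (patient, wall, st_mu)
    fields: dict                # (patient, wall, st_mu, probe) -> (sigma, eps)
    n_failed: int


def compare_conditions(values_a, values_b):
    """Welch two-sided t-test between two per-element field samples.

    Returns ``(t, dof, p)``; used to flag significant probe-pressure
    effects on the wall fields.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise MeasurementError("need at least 3 elements per sample")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _wall_factory(model: str, thickness: float, hgo_params, linear_params):
    if model == "hgo":
        return HGOWall(params=hgo_params, thickness=thickness)
    if model == "linear":
        return LinearWall(params=linear_params, thickness=thickness)
    raise ValueError(f"unknown wall model {model!r}")


def run_study(design: StudyDesign | None = None,
              archetypes: dict[str, GeometrySpec] | None = None,
              blood_pressures: dict[str, tuple[float, float]] | None = None,
              probe_levels: dict[str, float] | None = None,
              hgo_params=None, linear_params=None,
              controls: SolverControls | None = None,
              zp_tol: float = 0.05, zp_max_iter: int = 15,
              zp_include_tissue: bool = True,
              zp_accelerate: bool = True,
              keep_fields: bool = True) -> StudyResult:
    """Run the factorial study and collect results.

    Rows are ordered deterministically (patient, wall model, tissue modulus,
    probe level).  A failed run is recorded with its error message rather
    than dropped; ``n_failed`` counts them.

    The zero-pressure geometry is computed once per
    (patient, wall model, tissue modulus) — it does not depend on the probe
    condition — and shared across the three probe levels.
    """
    from .constitutive import HGOWallParams, LinearWallParams

    design = design or StudyDesign()
    archetypes = archetypes or patient_archetypes()
    blood_pressures = blood_pressures or ARCHETYPE_PRESSURES_MMHG
    from .protocol import PROBE_LEVELS
    probe_levels = probe_levels or PROBE_LEVELS
    hgo_params = hgo_params or HGOWallParams()
    linear_params = linear_params or LinearWallParams()
    controls = controls or SolverControls(n_steps=10)

    rows = []
    eli_rows = []
    fields = {}
    n_failed = 0

    meshes = {}
    for pat in design.patients:
        spec = archetypes[pat]
        meshes[pat] = triangulate(make_geometry(spec))
        log.info("meshed %s: %d nodes, %d triangles, %d wall elements",
                 pat, meshes[pat].n_nodes, len(meshes[pat].triangles),
                 len(meshes[pat].wall_segments))

    for pat in design.patients:
        mesh = meshes[pat]
        spec = archetypes[pat]
        bp = BloodPressure(*blood_pressures[pat])
        for wall_model in design.wall_models:
            wall = _wall_factory(wall_model, spec.wall_thickness,
                                 hgo_params, linear_params)
            for mu in design.st_moduli:
                tissue = TissueParams(mu=mu)
                base = {"patient": pat, "wall_model": wall_model,
                        "st_mu": mu}
                try:
                    if zp_include_tissue:
                        asm0 = ModelAssembly(
                            mesh, wall=wall, tissue=tissue,
                            lumen_pressure=bp.aortic_dias_kPa)
                    else:
                        # detached wall ring: freeze every non-wall node
                        # and pin the ring's rigid modes
                        wall_ids = mesh.node_sets["wall"]
                        non_wall = np.setdiff1d(np.arange(mesh.n_nodes),
                                                wall_ids)
                        pins = np.concatenate([
                            (2 * non_wall[:, None] + np.arange(2)).ravel(),
                            [2 * wall_ids[0], 2 * wall_ids[0] + 1,
                             2 * wall_ids[len(wall_ids) // 2] + 1]])
                        wall_only = type(mesh)(
                            nodes=mesh.nodes,
                            triangles=np.empty((0, 3), dtype=int),
                            wall_segments=mesh.wall_segments,
                            wall_thickness=mesh.wall_thickness,
                            node_sets=mesh.node_sets,
                            probe_edges=np.empty((0, 2), dtype=int),
                            provenance=mesh.provenance)
                        asm0 = ModelAssembly(
                            wall_only, wall=wall,
                            lumen_pressure=bp.aortic_dias_kPa,
                            clamped_nodes=np.empty(0, dtype=int),
                            extra_fixed_dofs=pins)
                    zp = compute_zero_pressure(
                        asm0, bp.aortic_dias_kPa, tol=zp_tol,
                        max_iter=zp_max_iter,
                        controls=SolverControls(n_steps=5),
                        accelerate=zp_accelerate)
                except Exception as exc:  # noqa: BLE001 - recorded, not lost
                    log.error("0P failed for %s: %s", base, exc)
                    for label in design.probe_levels:
                        rows.append({**base, "probe": label,
                                     "error": f"zero-pressure: {exc}"})
                    n_failed += len(design.probe_levels)
                    continue
                log.info("0P %s/%s/mu=%g: %d iterations, error %.4f mm",
                         pat, wall_model, mu, zp.iterations, zp.final_error)

                meas = {}
                for label in design.probe_levels:
                    probe = ProbeCondition(label, probe_levels[label])
                    row = {**base, "probe": label,
                           "probe_kPa": probe.magnitude_kPa,
                           "p_dias_kPa": bp.aortic_dias_kPa,
                           "p_sys_kPa": bp.aortic_sys_kPa,
                           "zp_iterations": zp.iterations,
                           "zp_error_mm": zp.final_error,
                           "error": ""}
                    try:
                        asm = ModelAssembly(
                            mesh, wall=wall, tissue=tissue,
                            reference_coords=zp.reference_coords,
                            lumen_pressure=bp.aortic_sys_kPa,
                            probe_pressure=probe.magnitude_kPa)
                        m = run_protocol(asm, bp, probe, controls)
                        s = stiffness(m, bp)
                        # stress at diastole+probe; cyclic strain dias->sys
                        sigma, _ = extract_wall_fields(
                            asm, m.dias_state, m.dias_state)
                        _, eps = extract_wall_fields(
                            asm, m.sys_state, m.dias_state)
                        summ = FieldSummary.from_fields(sigma, eps)
                        meas[label] = m
                        row.update(
                            D_dias=m.D_dias, D_sys=m.D_sys, dD=m.dD,
                            C_dias=m.C_dias, C_sys=m.C_sys, dC=m.dC,
                            beta_diam=s.beta_diam, beta_circ=s.beta_circ,
                            **vars(summ))
                        if keep_fields:
                            fields[(pat, wall_model, mu, label)] = (sigma,
                                                                    eps)
                    except Exception as exc:  # noqa: BLE001
                        log.error("run failed for %s: %s", row, exc)
                        row["error"] = str(exc)
                        n_failed += 1
                    rows.append(row)

                if "LPP" in meas and "FPP" in meas:
                    e = eli(meas["LPP"], meas["FPP"])
                    eli_rows.append({**base, "eli_diam": e.eli_diam,
                                     "eli_circ": e.eli_circ})

    runs = pd.DataFrame(rows)
    eli_df = pd.DataFrame(eli_rows)
    return StudyResult(runs=runs, eli=eli_df, fields=fields,
                       n_failed=n_failed)
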