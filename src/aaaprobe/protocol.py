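"""The in-silico ultrasound examination protocol.

A run emulates what a sonographer measures: with the probe pressed on the
abdomen at a given strength, the antero-posterior (AP) diameter ``D`` and
the wall circumference ``C`` of the aneurysm are read off at diastole and
systole.  Loading is staged the way the measurement is made: (1) ramp the
probe pressure to its target, (2) ramp the lumen pressure to diastole,
(3) raise it to systole at constant probe pressure.

Brachial cuff pressures are converted to abdominal aortic pressures before
loading (diastolic −12%, systolic +5%), then mmHg → kPa.

``D`` and ``C`` are measured on the deformed wall mid-surface: ``D`` as the
span of the two intersections of the mid-surface with the AP line (parallel
to the probe axis, +y) through the deformed lumen centroid, ``C`` as the
mid-surface polyline length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import MeasurementError
from .solver import (ModelAssembly, SolverControls, SolveState,
                     solve_static)

__all__ = [
    "MMHG_TO_KPA",
    "BloodPressure",
    "ProbeCondition",
    "MeasuredState",
    "brachial_to_aortic",
    "measure_wall",
    "run_protocol",
    "PROBE_LEVELS",
]

MMHG_TO_KPA = 0.1333224

#: Standard probe conditions: light / moderate / firm probe pressure (kPa).
PROBE_LEVELS = {"LPP": 2.0, "MPP": 15.0, "FPP": 30.0}


def brachial_to_aortic(dias_mmHg: float, sys_mmHg: float):
    """Brachial cuff pair (mmHg) → abdominal aortic pair (kPa).

    Diastolic pressure is decreased by 12% and systolic increased by 5%
    (pulse-pressure amplification between the brachial artery and the
    abdominal aorta), then converted to kPa.
    """
    if not sys_mmHg > dias_mmHg > 0:
        raise MeasurementError(
            f"non-physiologic brachial pair ({dias_mmHg}, {sys_mmHg}) mmHg")
    return (0.88 * dias_mmHg * MMHG_TO_KPA, 1.05 * sys_mmHg * MMHG_TO_KPA)


@dataclass(frozen=True)
class BloodPressure:
    """Brachial measurement and the derived aortic loading pressures."""

    brachial_dias_mmHg: float
    brachial_sys_mmHg: float
    aortic_dias_kPa: float = field(init=False)
    aortic_sys_kPa: float = field(init=False)

    def __post_init__(self):
        d, s = brachial_to_aortic(self.brachial_dias_mmHg,
                                  self.brachial_sys_mmHg)
        object.__setattr__(self, "aortic_dias_kPa", d)
        object.__setattr__(self, "aortic_sys_kPa", s)


@dataclass(frozen=True)
class ProbeCondition:
    """One probe-pressure condition, e.g. ``ProbeCondition.standard("FPP")``."""

    label: str
    magnitude_kPa: float

    @classmethod
    def standard(cls, label: str) -> "ProbeCondition":
        if label not in PROBE_LEVELS:
            raise MeasurementError(f"unknown probe level {label!r}")
        return cls(label=label, magnitude_kPa=PROBE_LEVELS[label])


@dataclass
class MeasuredState:
    """The in-silico ultrasound readings for one probe condition (mm)."""

    probe: ProbeCondition
    D_dias: float
    D_sys: float
    C_dias: float
    C_sys: float
    dias_state: SolveState | None = None
    sys_state: SolveState | None = None

    @property
    def dD(self) -> float:
        return self.D_sys - self.D_dias

    @property
    def dC(self) -> float:
        return self.C_sys - self.C_dias


def measure_wall(assembly: ModelAssembly, state: SolveState):
    """AP diameter and circumference of the deformed wall mid-surface.

    The AP line runs parallel to the probe axis (+y, fixed lab frame)
    through the deformed lumen centroid.
    """
    ids = assembly.mesh.node_sets["wall"]
    xy = assembly.reference_mesh_coords[ids] + state.displacements[ids]
    poly = Polygon(xy)
    if not poly.is_valid:
        raise MeasurementError("deformed wall mid-surface self-intersects")
    cx = poly.centroid.x
    ymin, ymax = xy[:, 1].min(), xy[:, 1].max()
    line = LineString([(cx, ymin - 10.0), (cx, ymax + 10.0)])
    cut = line.intersection(poly)
    if cut.is_empty:
        raise MeasurementError("AP line misses the wall mid-surface")
    ys = [c for g in getattr(cut, "geoms", [cut])
          for c in np.asarray(g.coords)[:, 1]]
    D = float(max(ys) - min(ys))
    closed = np.vstack([xy, xy[:1]])
    C = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    return D, C


def run_protocol(assembly: ModelAssembly, bp: BloodPressure,
                 probe: ProbeCondition,
                 controls: SolverControls | None = None,
                 keep_states: bool = True) -> MeasuredState:
    """Staged loading and measurement for one probe condition.

    ``assembly`` must be built on the load-free (zero-pressure) reference
    geometry with ``lumen_pressure`` and ``probe_pressure`` set to the
    systolic aortic pressure and the probe magnitude respectively; load
    factors then ramp probe → diastole → systole.
    """
    if assembly.probe_pressure != probe.magnitude_kPa:
        raise MeasurementError(
            "assembly probe_pressure does not match the probe condition")
    if assembly.lumen_pressure != bp.aortic_sys_kPa:
        raise MeasurementError(
            "assembly lumen_pressure must be the systolic aortic pressure")
    f_dias = bp.aortic_dias_kPa / bp.aortic_sys_kPa
    controls = controls or SolverControls(n_steps=10)

    # the probe ramp is the stiff part of the path; the pressurization and
    # the diastole->systole increment converge in fewer steps
    from dataclasses import replace as _replace
    stages = [("pressurize", (0.0, f_dias),
               _replace(controls, n_steps=max(3, controls.n_steps // 2))),
              ("probe", (1.0, f_dias), controls),
              ("systole", (1.0, 1.0),
               _replace(controls, n_steps=max(4, controls.n_steps // 2)))]
    state = None
    results = {}
    assembly.foundation_anchor = None
    assembly.foundation_force = None
    for name, target, ctl in stages:
        try:
            state = solve_static(assembly, target, ctl, state0=state)
        except Exception as exc:  # noqa: BLE001 - annotate the stage
            raise type(exc)(f"stage '{name}': {exc}") from exc
        if name == "pressurize":
            # anchor the out-of-plane correction at the no-probe diastolic
            # state: only probe-induced deviations feel the foundation
            assembly.foundation_anchor = state.u_full.copy()
        else:
            results[name] = (measure_wall(assembly, state), state)
            if name == "probe":
                # the z-uniform cyclic inflation must not feel the
                # foundation stiffness: keep its force, drop the spring
                assembly.freeze_foundation(state.u_full)

    # end of the "probe" stage = diastole at full probe pressure
    (D_d, C_d), st_d = results["probe"]
    (D_s, C_s), st_s = results["systole"]
    return MeasuredState(probe=probe, D_dias=D_d, D_sys=D_s,
                        C_dias=C_d, C_sys=C_s,
                        dias_state=st_d if keep_states else None,
                        sys_state=st_s if keep_states else None)
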