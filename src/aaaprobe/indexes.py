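"""Stiffness index β and Elasticity Loss Index (ELI).

The stiffness index relates the pulse-pressure ratio to the relative
distension over the cardiac cycle,

    β_diam = ln(P_sys/P_dias) / (ΔD/D_dias),
    β_circ = ln(P_sys/P_dias) / (ΔC/C_dias),

computed with the aortic (applied lumen) pressures; the logarithm makes β
insensitive to the pressure unit.  The Elasticity Loss Index is the ratio of
β at light vs. firm probe pressure,

    ELI = β_LPP / β_FPP = (Δx_FPP/Δx_LPP) · (x_dias,LPP/x_dias,FPP),

where the second (ultrasound-only) form follows because the pressure ratio
cancels.  ELI > 1 flags a nonlinear, J-shaped wall: firm probe pressure
unloads the wall toward its compliant toe region, lowering the measured β.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import MeasurementError
from .protocol import BloodPressure, MeasuredState, ProbeCondition

__all__ = ["StiffnessResult", "EliResult", "beta_index", "stiffness", "eli"]


def beta_index(p_dias: float, p_sys: float,
               x_dias: float, x_sys: float) -> float:
    """β = ln(p_sys/p_dias) · x_dias / (x_sys − x_dias).

    ``x`` is a diameter or circumference; any consistent pressure unit.
    A negative distension (x_sys < x_dias) returns a signed value.
    """
    if not p_sys > p_dias > 0:
        raise MeasurementError(f"need p_sys > p_dias > 0, got ({p_dias}, {p_sys})")
    if x_dias <= 0:
        raise MeasurementError("x_dias must be > 0")
    if x_sys == x_dias:
        raise MeasurementError("zero pulsatile distension")
    return math.log(p_sys / p_dias) * x_dias / (x_sys - x_dias)


@dataclass(frozen=True)
class StiffnessResult:
    """β indexes for one probe condition."""

    beta_diam: float
    beta_circ: float
    probe: ProbeCondition
    measurement: MeasuredState
    blood_pressure: BloodPressure


def stiffness(meas: MeasuredState, bp: BloodPressure) -> StiffnessResult:
    """Both β indexes from one measured state (aortic pressures)."""
    pd, ps = bp.aortic_dias_kPa, bp.aortic_sys_kPa
    return StiffnessResult(
        beta_diam=beta_index(pd, ps, meas.D_dias, meas.D_sys),
        beta_circ=beta_index(pd, ps, meas.C_dias, meas.C_sys),
        probe=meas.probe, measurement=meas, blood_pressure=bp)


@dataclass(frozen=True)
class EliResult:
    """Elasticity Loss Indexes from the LPP and FPP conditions."""

    eli_diam: float
    eli_circ: float
    lpp_state: MeasuredState
    fpp_state: MeasuredState


def eli(meas_lpp: MeasuredState, meas_fpp: MeasuredState,
        check_identity_tol: float = 1.0e-9) -> EliResult:
    """ELI from the light- and firm-probe measurements.

    Uses the ultrasound-only form (Δx ratio times diastolic-size ratio) and
    verifies the algebraic identity with the β ratio to machine precision
    (the blood-pressure ratio cancels between the two forms).
    """
    for m in (meas_lpp, meas_fpp):
        if m.dD == 0.0 or m.dC == 0.0:
            raise MeasurementError(
                f"zero pulsatile distension under {m.probe.label}")
    eli_d = (meas_fpp.dD / meas_lpp.dD) * (meas_lpp.D_dias / meas_fpp.D_dias)
    eli_c = (meas_fpp.dC / meas_lpp.dC) * (meas_lpp.C_dias / meas_fpp.C_dias)

    # cross-check against the beta-ratio form with an arbitrary pressure pair
    pd, ps = 10.0, 16.0
    ratio_d = (beta_index(pd, ps, meas_lpp.D_dias, meas_lpp.D_sys)
               / beta_index(pd, ps, meas_fpp.D_dias, meas_fpp.D_sys))
    ratio_c = (beta_index(pd, ps, meas_lpp.C_dias, meas_lpp.C_sys)
               / beta_index(pd, ps, meas_fpp.C_dias, meas_fpp.C_sys))
    for a, b, name in ((eli_d, ratio_d, "diam"), (eli_c, ratio_c, "circ")):
        if abs(a - b) > check_identity_tol * max(abs(a), abs(b)):
            raise MeasurementError(
                f"ELI_{name} identity violated: {a!r} vs beta ratio {b!r}")
    return EliResult(eli_diam=eli_d, eli_circ=eli_c,
                     lpp_state=meas_lpp, fpp_state=meas_fpp)
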