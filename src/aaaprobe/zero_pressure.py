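"""Load-free (zero-pressure, "0P") reference configuration.

The imaged anatomy is acquired at diastole, i.e. pressurized.  A stress
analysis needs the load-free geometry, which is recovered by the classic
backward-displacement iteration: inflate the current candidate reference to
diastolic pressure (no probe load, homogeneous lumen pressure), subtract the
obtained displacement field from the imaged coordinates, repeat until the
re-inflated candidate matches the imaged geometry.

The forward inflation includes the surrounding tissue (wall and tissue are
tied, so the wall cannot be inflated in isolation); this can be switched off
to inflate a detached wall ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ZeroPressureError
from .solver import ModelAssembly, SolverControls, SolveState, solve_static

__all__ = ["ZeroPressureResult", "compute_zero_pressure"]


@dataclass
class ZeroPressureResult:
    reference_coords: np.ndarray     # (n_nodes, 2) mm, load-free geometry
    iterations: int
    final_error: float               # mm, max nodal mismatch at p_dias
    history: list[float]             # per-iteration error
    converged: bool
    inflated_state: SolveState       # last forward solve (candidate -> dias)


def compute_zero_pressure(assembly: ModelAssembly, p_dias: float,
                          tol: float = 0.05, max_iter: int = 15,
                          controls: SolverControls | None = None,
                          accelerate: bool = True) -> ZeroPressureResult:
    """Backward-displacement iteration for the load-free geometry.

    ``assembly`` must be built on the target (imaged, diastolic) geometry.
    Update rule: ``X_(k+1) = X_target − U_k`` where ``U_k`` is the nodal
    displacement from inflating candidate ``X_(k)`` to ``p_dias`` with no
    probe load.  Stops when the max nodal error drops below ``tol`` (mm).

    With ``accelerate=True`` the fixed-point update is Aitken-relaxed:
    ``X_(k+1) = X_k + ω_k Δ_k`` with ``Δ_k = X_target − U_k − X_k`` and the
    scalar ω adapted from successive updates.  This does not change the
    fixed point (Δ = 0 ⇔ the plain update is stationary), only the rate.

    Raises :class:`ZeroPressureError` if a forward solve diverges or the
    error grows for three consecutive iterations.
    """
    X_target = assembly.reference_mesh_coords.copy()
    if p_dias < 0:
        raise ZeroPressureError("p_dias must be >= 0")
    if p_dias == 0.0:
        state = solve_static(_rebuild(assembly, X_target), (0.0, 0.0),
                             controls)
        return ZeroPressureResult(reference_coords=X_target, iterations=1,
                                  final_error=0.0, history=[0.0],
                                  converged=True, inflated_state=state)

    X = X_target.copy()
    history: list[float] = []
    state = None
    growth = 0
    omega = 1.0
    delta_prev = None
    for k in range(1, max_iter + 1):
        asm_k = _rebuild(assembly, X, lumen_pressure=p_dias)
        try:
            state = solve_static(asm_k, (0.0, 1.0), controls)
        except Exception as exc:  # noqa: BLE001 - annotate iteration index
            raise ZeroPressureError(
                f"forward solve diverged at 0P iteration {k}: {exc}",
                iteration=k) from exc
        err = float(np.max(np.linalg.norm(
            X + state.displacements - X_target, axis=1)))
        history.append(err)
        if err < tol:
            return ZeroPressureResult(reference_coords=X, iterations=k,
                                      final_error=err, history=history,
                                      converged=True, inflated_state=state)
        if len(history) >= 2 and err > history[-2]:
            growth += 1
            if growth >= 3:
                raise ZeroPressureError(
                    f"0P not contracting: error grew 3 consecutive "
                    f"iterations (history {history})", iteration=k)
        else:
            growth = 0
        delta = X_target - state.displacements - X   # plain update increment
        if accelerate and delta_prev is not None:
            dd = delta - delta_prev
            denom = float(np.sum(dd * dd))
            if denom > 0.0:
                omega = float(np.clip(
                    -omega * np.sum(delta_prev * dd) / denom, 0.5, 8.0))
        delta_prev = delta
        X = X + omega * delta                       # ω=1: X_target - U_k
    return ZeroPressureResult(reference_coords=X, iterations=max_iter,
                              final_error=history[-1], history=history,
                              converged=False, inflated_state=state)


def _rebuild(assembly: ModelAssembly, reference_coords,
             lumen_pressure: float = 0.0) -> ModelAssembly:
    """Same mesh/materials/BCs on a different reference configuration."""
    return ModelAssembly(
        assembly.mesh, wall=assembly.wall, tissue=assembly.tissue,
        reference_coords=reference_coords,
        lumen_pressure=lumen_pressure, probe_pressure=0.0,
        element_order=assembly.element_order,
        clamped_nodes=assembly.clamped_nodes,
        extra_fixed_dofs=assembly.extra_fixed_dofs)
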