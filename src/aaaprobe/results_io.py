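"""Result serialization: CSV tables, JSON summary, legacy-VTK meshes.

Output is deterministic byte-for-byte for fixed inputs: fixed column order,
fixed float formatting, sorted JSON keys.  Every results directory carries
the fully resolved configuration and the package version for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import AAAProbeError

__all__ = ["write_results", "write_vtk"]

RUN_COLUMNS = [
    "patient", "wall_model", "st_mu", "probe", "probe_kPa",
    "p_dias_kPa", "p_sys_kPa",
    "D_dias", "D_sys", "dD", "C_dias", "C_sys", "dC",
    "beta_diam", "beta_circ",
    "n_elements", "sigma_min", "sigma_q1", "sigma_median", "sigma_q3",
    "sigma_max", "eps_q1", "eps_median", "eps_q3",
    "zp_iterations", "zp_error_mm", "error",
]

ELI_COLUMNS = ["patient", "wall_model", "st_mu", "eli_diam", "eli_circ"]

_FLOAT_FMT = "%.10g"


def write_results(result, config, out_dir) -> dict[str, Path]:
    """Write ``runs.csv``, ``eli.csv``, ``summary.json`` and the resolved
    config; returns the paths written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise AAAProbeError(f"cannot create output directory {out}: {exc}")

    runs = result.runs.reindex(columns=RUN_COLUMNS)
    eli = result.eli.reindex(columns=ELI_COLUMNS)
    paths = {}
    paths["runs"] = out / "runs.csv"
    runs.to_csv(paths["runs"], index=False, float_format=_FLOAT_FMT)
    paths["eli"] = out / "eli.csv"
    eli.to_csv(paths["eli"], index=False, float_format=_FLOAT_FMT)

    summary = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "n_runs": int(len(runs)),
        "n_failed": int(result.n_failed),
        "n_eli_rows": int(len(eli)),
    }
    if len(eli):
        for wall in sorted(eli["wall_model"].unique()):
            sub = eli[eli["wall_model"] == wall]
            summary[f"eli_circ_{wall}_mean"] = float(sub["eli_circ"].mean())
            summary[f"eli_diam_{wall}_mean"] = float(sub["eli_diam"].mean())
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, sort_keys=True,
                                           indent=2) + "\n")
    paths["config"] = out / "config.resolved.yaml"
    paths["config"].write_text(config.dump_yaml())
    return paths


def write_vtk(path, mesh, point_displacements=None, cell_data=None,
              wall_data=None):
    """Write a legacy-ASCII VTK unstructured grid of the tissue mesh.

    ``point_displacements`` (n, 2) are written as a 3-component vector
    field; ``cell_data`` maps names to per-triangle arrays.  Wall membrane
    segments are appended as VTK line cells, with ``wall_data`` arrays
    padded over the triangles.
    """
    path = Path(path)
    nodes = np.asarray(mesh.nodes, dtype=float)
    tris = np.asarray(mesh.triangles, dtype=int)
    segs = np.asarray(mesh.wall_segments, dtype=int)
    n_cells = len(tris) + len(segs)

    lines = ["# vtk DataFile Version 3.0", "aaaprobe cross-section model",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    for x, y in nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {n_cells} {4 * len(tris) + 3 * len(segs)}")
    for t in tris:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    for s in segs:
        lines.append(f"2 {s[0]} {s[1]}")
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["5"] * len(tris))     # VTK_TRIANGLE
    lines.extend(["3"] * len(segs))     # VTK_LINE

    if point_displacements is not None:
        u = np.asarray(point_displacements, dtype=float)
        lines.append(f"POINT_DATA {len(nodes)}")
        lines.append("VECTORS displacement double")
        for ux, uy in u:
            lines.append(f"{ux:.10g} {uy:.10g} 0")

    cell_fields = dict(cell_data or {})
    for name, arr in (wall_data or {}).items():
        full = np.zeros(n_cells)
        full[len(tris):] = np.asarray(arr, dtype=float)
        cell_fields[name] = full
    if cell_fields:
        lines.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_fields.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) == len(tris):
                arr = np.concatenate([arr, np.zeros(len(segs))])
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.10g}" for v in arr)
    path.write_text("\n".join(lines) + "\n")
    return path
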