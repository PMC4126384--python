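"""File I/O: curves and traces as CSV, fields as legacy ASCII VTK, geometry
as JSON, plus the synthetic target-curve fixture.

The experimental tension curve the inverse procedure was designed for is not
available as a table, so :func:`synth_target_curve` synthesizes a stand-in
from the incompressible uniaxial Ogden law at the published curve-fit
parameters (shear modulus 32.8 kPa, exponent 8.22).  Legacy ASCII VTK was
chosen for field export because it is human-readable and needs no binary
dependencies.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import OgdenMaterial, uniaxial_nominal_stress
from .errors import ConfigurationError
from .fe import HomogenizedResult, Mesh
from .geometry import RVEGeometry
from .inverse import SearchTrace, StressStretchCurve

__all__ = [
    "synth_target_curve",
    "read_curve_csv",
    "write_curve_csv",
    "write_trace_csv",
    "write_vtk_hex",
    "write_vtk_polylines",
    "write_results",
]


def synth_target_curve(mu_fit: float = 32.8, alpha: float = 8.22,
                       lambda_max: float = 1.25,
                       n_points: int = 50) -> StressStretchCurve:
    """Synthetic uniaxial Ogden target curve, tagged ``synthetic``.

    Returns ``n_points + 1`` samples at equidistant stretches from 1 (where
    the stress is exactly zero) to ``lambda_max``.
    """
    if mu_fit <= 0:
        raise ConfigurationError("mu_fit must be positive")
    lam = np.linspace(1.0, lambda_max, n_points + 1)
    mat = OgdenMaterial(mu_fit, alpha)
    return StressStretchCurve(lam, uniaxial_nominal_stress(lam, mat),
                              source="synthetic")


def write_curve_csv(curve: StressStretchCurve, path,
                    header: tuple[str, str] = ("lambda", "S33_kPa")) -> None:
    pd.DataFrame({header[0]: curve.stretches,
                  header[1]: curve.stresses}).to_csv(path, index=False)


def read_curve_csv(path, source: str = "experimental") -> StressStretchCurve:
    """Read a two-column (stretch, nominal stress in kPa) CSV curve.

    The first column is taken as stretch and the second as stress whatever
    the header names; a stretch = 1 row is optional.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ConfigurationError(f"curve file {path} needs two columns")
    return StressStretchCurve(df.iloc[:, 0].to_numpy(dtype=float),
                              df.iloc[:, 1].to_numpy(dtype=float),
                              source=source)


def write_trace_csv(trace: SearchTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def _vtk_header(fh, title: str):
    fh.write("# vtk DataFile Version 2.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write("DATASET UNSTRUCTURED_GRID\n")


def write_vtk_hex(mesh: Mesh, path, point_data: dict | None = None,
                  cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid of the hexahedral matrix mesh.

    ``point_data`` maps names to (n_nodes,) scalars or (n_nodes, 3) vectors;
    ``cell_data`` maps names to per-element scalars.
    """
    with open(path, "w") as fh:
        _vtk_header(fh, "axonrve matrix mesh")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {9 * ne}\n")
        cells = np.column_stack([np.full(ne, 8), mesh.connectivity])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12), fmt="%d")  # VTK_HEXAHEDRON
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
        if cell_data:
            fh.write(f"CELL_DATA {ne}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr).reshape(-1, 1), fmt="%.9g")


def write_vtk_polylines(polylines, path, title: str = "axonrve fibers") -> None:
    """Legacy ASCII VTK polylines (one per axon centerline or fiber chain)."""
    polylines = [np.asarray(p, dtype=float) for p in polylines]
    n_pts = sum(len(p) for p in polylines)
    with open(path, "w") as fh:
        _vtk_header(fh, title)
        fh.write(f"POINTS {n_pts} double\n")
        for p in polylines:
            np.savetxt(fh, p, fmt="%.9g")
        n_lines = len(polylines)
        total = sum(len(p) + 1 for p in polylines)
        fh.write(f"CELLS {n_lines} {total}\n")
        offset = 0
        for p in polylines:
            ids = " ".join(str(offset + k) for k in range(len(p)))
            fh.write(f"{len(p)} {ids}\n")
            offset += len(p)
        fh.write(f"CELL_TYPES {n_lines}\n")
        np.savetxt(fh, np.full(n_lines, 4), fmt="%d")  # VTK_POLY_LINE


def write_results(outdir, config, rve: RVEGeometry | None = None,
                  result: HomogenizedResult | None = None,
                  trace: SearchTrace | None = None,
                  curves: dict[str, StressStretchCurve] | None = None) -> Path:
    """Write a self-describing output directory.

    Always echoes the validated configuration (YAML, including the seed);
    optionally writes the geometry JSON + centerline VTK, the homogenized
    curve CSV, VTK fields, the tortuosity table, the search trace, and any
    named curves.  Re-running from the echoed configuration and seed
    reproduces every CSV to round-off.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    if rve is not None:
        rve.to_json(out / "geometry.json")
        write_vtk_polylines([a.centerline for a in rve.axons],
                            out / "centerlines.vtk")
    if result is not None:
        pd.DataFrame({"lambda": result.stretches,
                      "S33_kPa": result.stresses}).to_csv(
            out / "curve.csv", index=False)
        from .fe import tortuosity_trace

        tortuosity_trace(result).to_csv(out / "tortuosity.csv", index=False)
        if result.final_state is not None:
            st = result.final_state
            mesh = st.model.mesh
            from .fe import von_mises_field

            u_mat = st.u[: 3 * mesh.n_nodes].reshape(-1, 3)
            write_vtk_hex(mesh, out / "fields.vtk",
                          point_data={"displacement": u_mat},
                          cell_data={"von_mises_kPa": von_mises_field(st)})
            write_vtk_polylines(st.axon_deformed_nodes(), out / "fibers.vtk",
                                title="axonrve deformed fibers")
    if trace is not None:
        write_trace_csv(trace, out / "trace.csv")
    for name, curve in (curves or {}).items():
        write_curve_csv(curve, out / f"{name}.csv")
    return out
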