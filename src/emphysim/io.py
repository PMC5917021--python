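"""Export helpers: VTU meshes and state snapshots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import ABState, CONC_FIELDS
from .mechanics import QuadMesh

__all__ = ["write_vtu", "ab_state_to_frame", "save_ab_snapshot"]


def write_vtu(
    mesh: QuadMesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the quad mesh and attached fields as an ASCII VTU file.

    Point data may be scalar (n_nodes,) or vector (n_nodes, 2/3); cell data
    must be scalar per element.  The format is the plain XML VTK
    unstructured grid, readable by ParaView and meshio.
    """
    def fmt(a):
        return " ".join(f"{v:.10g}" for v in np.asarray(a, dtype=float).ravel())

    pts = np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)])
    conn = mesh.elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        fmt(pts),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        fmt(conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        fmt(4 * (np.arange(mesh.n_elements) + 1)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["9"] * mesh.n_elements),
        "</DataArray>", "</Cells>",
    ]
    lines.append("<PointData>")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if ncomp == 2:  # pad 2D vectors to 3 components for VTK
            arr = np.column_stack([arr, np.zeros(arr.shape[0])])
            ncomp = 3
        lines += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{ncomp}" format="ascii">', fmt(arr),
                  "</DataArray>"]
    lines.append("</PointData>")
    lines.append("<CellData>")
    for name, arr in (cell_data or {}).items():
        lines += [f'<DataArray type="Float64" Name="{name}" format="ascii">',
                  fmt(arr), "</DataArray>"]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def ab_state_to_frame(state: ABState) -> pd.DataFrame:
    """Per-cell column table of the agent-grid state (row-major order)."""
    rows, cols = state.shape
    rr, cc = np.divmod(np.arange(state.n_cells), cols)
    data = {
        "row": rr, "col": cc,
        "tissue_life": state.tissue_life.ravel(),
        "alive": state.alive.ravel().astype(int),
        "cel": state.cel.ravel(),
        "ccl": state.ccl.ravel(),
        "particles": state.particles.ravel(),
        "C": state.C.ravel(),
    }
    for name in CONC_FIELDS:
        data[name] = state.conc[name].ravel()
    return pd.DataFrame(data)


def save_ab_snapshot(state: ABState, out_dir) -> None:
    """Dump the grid as CSV and the agent list as JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ab_state_to_frame(state).to_csv(out / f"cells_{state.step_count:06d}.csv",
                                    index=False)
    agents = [{"kind": a.kind.value, "row": a.row, "col": a.col, "age": a.age}
              for a in state.agents]
    (out / f"agents_{state.step_count:06d}.json").write_text(
        json.dumps({"step": state.step_count, "agents": agents}))
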