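"""Plain-text output formats: legacy-ASCII VTK, CSV tables, YAML configs.

The VTK writer emits the classic ``UNSTRUCTURED_GRID`` text dialect with
point- and cell-data arrays, which every VTK-family viewer reads.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .meshing import Mesh


def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "laa_stasis") -> None:
    """Write the mesh and attached fields as a legacy ASCII VTK file."""
    path = Path(path)
    pts = mesh.vertices
    cells = mesh.cells
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        fh.write(f"\nCELLS {len(cells)} {4 * len(cells)}\n")
        for a, b, c in cells:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"\nCELL_TYPES {len(cells)}\n")
        fh.write("5\n" * len(cells))  # VTK_TRIANGLE

        def _write_arrays(data: dict, n: int) -> None:
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.10g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        z = row[2] if arr.shape[1] > 2 else 0.0
                        fh.write(f"{row[0]:.10g} {row[1]:.10g} {z:.10g}\n")

        if point_data:
            fh.write(f"\nPOINT_DATA {len(pts)}\n")
            _write_arrays(point_data, len(pts))
        if cell_data:
            fh.write(f"\nCELL_DATA {len(cells)}\n")
            _write_arrays(cell_data, len(cells))


def write_state_vtk(path, mesh: Mesh, state, extra_cell_data: dict | None = None) -> None:
    """Snapshot of a :class:`~laa_stasis.solver.FlowState`."""
    region_id = (
        (mesh.region == "LAA").astype(float) if mesh.region is not None else None
    )
    cell_data = {"contrast": state.c}
    if region_id is not None:
        cell_data["laa_region"] = region_id
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    write_vtk(
        path,
        mesh,
        point_data={
            "velocity": np.column_stack([state.u, state.v]),
            "pressure": state.p,
        },
        cell_data=cell_data,
        title=f"t={state.t:.6f}",
    )


def waveform_to_csv(wf, path, dt: float = 5e-4) -> None:
    """Tabulate one cycle of a waveform as (t, v) CSV."""
    import pandas as pd

    t = np.arange(0.0, wf.T + 0.5 * dt, dt)
    pd.DataFrame({"t": t, "v": wf(t)}).to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj: dict) -> str:
    """Short provenance hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
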