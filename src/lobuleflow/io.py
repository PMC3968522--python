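"""Export of meshes, fields and reports.

Meshes and nodal fields are written as legacy-VTK ASCII unstructured
grids (readable by ParaView and friends); tabular summaries as delimited
text; contour figures via matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import CellMesh, Mesh
from .parameters import MMHG
from .solver import PressureFields, compute_darcy_velocities, compute_exchange_fields


def write_vtk(mesh: Mesh, fields: PressureFields | None, path: str | Path) -> None:
    """Write the (multi-cell) mesh and nodal fields as a legacy-VTK ASCII file."""
    path = Path(path)
    pts = np.vstack([c.points for c in mesh.cells])
    offs = np.cumsum([0] + [len(c.points) for c in mesh.cells])
    tris = np.vstack([c.triangles + o for c, o in zip(mesh.cells, offs)])

    lines = ["# vtk DataFile Version 3.0", "lobuleflow export", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(pts)} double"]
    lines += [f"{x:.9e} {y:.9e} 0.0" for x, y in pts]
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    lines.append(f"CELL_TYPES {len(tris)}")
    lines += ["5"] * len(tris)

    if fields is not None:
        pS = np.full(len(pts), np.nan)
        pI = np.empty(len(pts))
        for k, c in enumerate(mesh.cells):
            sl = slice(offs[k], offs[k + 1])
            pI[sl] = fields.p_I[mesh.pI_maps[k]]
            if c.region == "tissue":
                pS[sl] = fields.p_S[k]
        ex = compute_exchange_fields(fields)
        qw = np.full(len(pts), np.nan)
        ql = np.empty(len(pts))
        for k, c in enumerate(mesh.cells):
            sl = slice(offs[k], offs[k + 1])
            ql[sl] = ex.q_l[mesh.pI_maps[k]]
            if c.region == "tissue":
                qw[sl] = ex.q_w[k]
        lines.append(f"POINT_DATA {len(pts)}")
        for name, arr in (("p_S_mmHg", pS / MMHG), ("p_I_mmHg", pI / MMHG),
                          ("q_w_per_s", qw), ("q_l_per_s", ql)):
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [f"{v:.9e}" for v in arr]
    path.write_text("\n".join(lines) + "\n")


def plot_pressure_contours(fields: PressureFields, path: str | Path,
                           which: str = "both") -> None:
    """Filled contour plots of p_S and/or p_I over all tissue cells [mmHg]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.tri import Triangulation

    panels = ["S", "I"] if which == "both" else [which]
    fig, axes = plt.subplots(1, len(panels), figsize=(5.2 * len(panels), 5.0))
    axes = np.atleast_1d(axes)
    for ax, w in zip(axes, panels):
        vmin = vmax = None
        for k, c in enumerate(fields.mesh.cells):
            if c.region != "tissue" and w == "S":
                continue
            v = (fields.p_S[k] if w == "S"
                 else fields.p_I[fields.mesh.pI_maps[k]]) / MMHG
            tri = Triangulation(c.points[:, 0] * 1e6, c.points[:, 1] * 1e6,
                                c.triangles)
            cs = ax.tricontourf(tri, v, levels=20, cmap="viridis",
                                vmin=vmin, vmax=vmax)
        fig.colorbar(cs, ax=ax, label=f"p_{w} [mmHg]")
        ax.set_aspect("equal")
        ax.set_xlabel("x [um]")
        ax.set_ylabel("y [um]")
        ax.set_title(f"{'sinusoidal' if w == 'S' else 'interstitial'} pressure")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_flux_report(summary_dict: dict, path: str | Path) -> None:
    """Key-value flux report as delimited text."""
    lines = [f"{k}\t{v:.6g}" for k, v in summary_dict.items()]
    Path(path).write_text("\n".join(lines) + "\n")
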