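"""Result serialization: HDF5 states, CSV tables, Matrix Market exports."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .assembly import GeneratorMatrix, StructureReport, compartmental_graph
from .dynamics import PDFVector, Trajectory
from .stationary import StationarySolution

__all__ = [
    "write_matrix_market",
    "write_edge_list",
    "write_stationary",
    "write_trajectory",
    "structure_report_text",
]


def write_matrix_market(G: GeneratorMatrix, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(G.matrix))


def write_edge_list(G: GeneratorMatrix, path: str | Path) -> None:
    """Plain-text edge list: source, target, rate (one edge per line)."""
    edges = compartmental_graph(G)
    with open(path, "w") as fh:
        fh.write("# source target rate\n")
        for s, t, r in edges:
            fh.write(f"{s} {t} {r:.17g}\n")


def _grid_attrs(group, grid) -> None:
    group.attrs["N"] = np.asarray(grid.N)
    group.attrs["L"] = np.asarray(grid.L)
    group.attrs["h"] = np.asarray(grid.h)
    group.attrs["cell_volume"] = grid.cell_volume


def write_stationary(sol: StationarySolution, h5_path: str | Path, csv_path: str | Path | None = None) -> None:
    """HDF5 (grid metadata + pbar) and, for 1-D, a midpoint/value CSV."""
    grid = sol.pbar.grid
    with h5py.File(h5_path, "w") as fh:
        _grid_attrs(fh, grid)
        fh.attrs["method"] = sol.method
        fh.attrs["residual_inf"] = sol.residual_inf
        fh.attrs["mass_defect"] = sol.mass_defect
        if grid.n >= 2:
            fh.create_dataset("pbar", data=sol.pbar.values.reshape(grid.N))
        else:
            fh.create_dataset("pbar", data=sol.pbar.values)
    if csv_path is not None and grid.n == 1:
        pd.DataFrame(
            {"midpoint": grid.midpoints_1d(0), "pbar": sol.pbar.values}
        ).to_csv(csv_path, index=False)


def write_trajectory(
    traj: Trajectory,
    h5_path: str | Path,
    csv_path: str | Path | None = None,
    pbar: PDFVector | None = None,
    gamma_ref: float = 1.0,
) -> None:
    """Trajectory snapshots to HDF5 plus a diagnostics CSV.

    Diagnostics: time, dimensionless tau = t * gamma_ref, mass and, when an
    equilibrium is supplied, the Lyapunov value and L1 distance to it.
    """
    with h5py.File(h5_path, "w") as fh:
        _grid_attrs(fh, traj.grid)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("states", data=traj.states)
        fh.create_dataset("mass", data=traj.mass)
        if pbar is not None:
            fh.create_dataset("lyapunov", data=traj.lyapunov_series(pbar))
    if csv_path is not None:
        cols = {"t": traj.times, "tau": traj.times * gamma_ref, "mass": traj.mass}
        if pbar is not None:
            cols["lyapunov"] = traj.lyapunov_series(pbar)
            cols["l1_to_equilibrium"] = traj.l1_series(pbar)
        pd.DataFrame(cols).to_csv(csv_path, index=False)


def structure_report_text(rep: StructureReport, nnz: int, predicted_nnz: int) -> str:
    lines = [
        f"metzler sign pattern : {'pass' if rep.metzler else 'FAIL'}",
        f"max |column sum|     : {rep.max_abs_column_sum:.3e}",
        f"strongly connected   : {'yes' if rep.strongly_connected else 'NO'}",
        f"complexes            : {rep.n_complexes}",
        f"linkage classes      : {rep.n_linkage_classes}",
        f"stoichiometric rank  : {rep.stoichiometric_rank} ({rep.rank_method})",
        f"deficiency           : {rep.deficiency}",
        f"nonzeros             : {nnz} (predicted {predicted_nnz})",
    ]
    return "\n".join(lines) + "\n"
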