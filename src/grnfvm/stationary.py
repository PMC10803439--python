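"""Stationary distribution via the rank-completed linear solve.

The Kirchhoff generator has a one-dimensional left kernel spanned by the
all-ones vector, so any N-1 of its rows are independent.  Replacing the
first row with h * ones^T turns the singular equilibrium condition into the
nonsingular system  Ghat pbar = e_1, whose unique solution is the strictly
positive stationary cell-average vector with unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import gmres, splu, spilu, LinearOperator

from .assembly import GeneratorMatrix
from .dynamics import NEG_DUST, PDFVector, default_dt, initial_pdf, l1_distance

__all__ = [
    "StationarySolution",
    "stationary_solve",
    "stationary_by_integration",
    "marginal_pdf",
]


@dataclass
class StationarySolution:
    """Stationary PDF with solve residuals and solver metadata."""

    pbar: PDFVector
    residual_inf: float  # || Gtilde pbar ||_inf
    mass_defect: float  # | h * sum(pbar) - 1 |
    method: str
    iterations: int = 0


def _rank_completed(G: GeneratorMatrix) -> sp.csc_matrix:
    """Ghat: the generator with row 0 replaced by h * ones^T."""
    A = G.matrix.tocsr(copy=True)
    h = G.grid.cell_volume
    N = G.grid.size
    top = sp.csr_matrix((np.full(N, h), (np.zeros(N, dtype=int), np.arange(N))), shape=(1, N))
    return sp.csc_matrix(sp.vstack([top, A[1:, :]], format="csr"))


def _package(G: GeneratorMatrix, pbar: np.ndarray, method: str, iterations: int = 0) -> StationarySolution:
    worst = pbar.min()
    if worst < -NEG_DUST:
        raise RuntimeError(
            f"stationary solve produced component {worst:.3e}; the generator "
            "is structurally broken (a valid Kirchhoff matrix has a positive "
            "equilibrium)"
        )
    pbar = np.where(pbar < 0, 0.0, pbar)
    residual = float(np.abs(G.matrix @ pbar).max())
    sol = PDFVector(pbar, G.grid)
    mass_defect = abs(sol.mass - 1.0)
    if mass_defect > 1e-10:
        raise RuntimeError(f"stationary mass defect {mass_defect:.3e} exceeds 1e-10")
    return StationarySolution(
        pbar=sol, residual_inf=residual, mass_defect=mass_defect, method=method, iterations=iterations
    )


def stationary_solve(G: GeneratorMatrix, method: str = "direct", tol: float = 1e-12) -> StationarySolution:
    """Solve Ghat pbar = e_1 for the unique stationary distribution.

    ``method`` is "direct" (sparse LU, default) or "iterative" (GMRES with
    an incomplete-LU preconditioner, for large multidimensional grids).
    """
    A = _rank_completed(G)
    e1 = np.zeros(G.grid.size)
    e1[0] = 1.0
    if method == "direct":
        try:
            pbar = splu(A).solve(e1)
        except RuntimeError as err:  # singular factorization
            raise RuntimeError(
                "rank-completed matrix is singular; the assembled generator "
                "is not strongly connected or not Kirchhoff"
            ) from err
        return _package(G, pbar, "direct")
    if method == "iterative":
        ilu = spilu(A, drop_tol=1e-6, fill_factor=20)
        M = LinearOperator(A.shape, ilu.solve)
        count = {"it": 0}

        def cb(_):
            count["it"] += 1

        pbar, info = gmres(A, e1, M=M, rtol=tol, atol=0.0, callback=cb, callback_type="pr_norm")
        if info != 0:
            raise RuntimeError(f"GMRES failed to converge (info={info})")
        return _package(G, pbar, "iterative", iterations=count["it"])
    raise ValueError(f"unknown method {method!r}")


def stationary_by_integration(
    G: GeneratorMatrix,
    tol: float = 1e-10,
    dt: float | None = None,
    max_steps: int = 500_000,
) -> StationarySolution:
    """Approximate the equilibrium by long-time backward-Euler integration.

    Starts from the uniform PDF and iterates the resolvent until the
    per-step L1 change drops below ``tol``.  Independent cross-check of
    :func:`stationary_solve` (power-type iteration vs direct solve).
    """
    from scipy.sparse.linalg import splu as _splu

    if dt is None:
        scale = np.abs(G.matrix.diagonal()).max()
        dt = 1.0 / scale if scale > 0 else 1.0
    N = G.grid.size
    lu = _splu(sp.csc_matrix(sp.identity(N) - dt * G.matrix))
    p = initial_pdf(G.grid, "uniform").values
    h = G.grid.cell_volume
    for k in range(1, max_steps + 1):
        q = lu.solve(p)
        change = h * np.abs(q - p).sum()
        p = q
        if change < tol:
            p = np.where((p < 0) & (p > -NEG_DUST), 0.0, p)
            return _package(G, p, "integration", iterations=k)
    raise RuntimeError(f"no convergence to per-step L1 change {tol} within {max_steps} steps")


def marginal_pdf(p: PDFVector, dim: int) -> PDFVector:
    """1-D marginal along ``dim``: sum over the other axes weighted by the
    transverse cell volume h / h_dim; unit mass under weight h_dim."""
    grid = p.grid
    if not 0 <= dim < grid.n:
        raise IndexError(f"dimension {dim} out of range for n={grid.n}")
    if grid.n == 1:
        return PDFVector(p.values.copy(), grid)
    axes = tuple(k for k in range(grid.n) if k != dim)
    transverse = grid.cell_volume / grid.h[dim]
    values = p.values.reshape(grid.N).sum(axis=axes) * transverse
    from .mesh import TruncatedGrid

    return PDFVector(values, TruncatedGrid([grid.N[dim]], [grid.L[dim]]))
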