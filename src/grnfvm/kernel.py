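"""Averaged burst-kernel coefficients and cell averages of coefficient fields.

The burst kernel along dimension ``i`` is beta(x) = omega(x) - delta(x),
where omega is the exponential burst-size density with mean ``b`` and delta
is the Dirac distribution (a burst removes the cell's own mass and lands it
at larger protein counts).  All averaged coefficients are evaluated from the
exact antiderivative of the exponential, so the geometric decay of the
off-diagonal series and the zero column sums hold to machine precision.

On the truncated domain, burst mass that would overshoot ``L_i`` is routed
into the last cell of dimension ``i`` (the protein count saturates at the
boundary); the last cell's own-burst coefficient is zero.  This is the
unique redistribution that keeps every source column exactly conservative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .mesh import TruncatedGrid
from .model import GRNModel, eval_degradation, eval_regulation

__all__ = [
    "BurstKernelCoefficients",
    "CellAverages",
    "burst_coefficients",
    "cell_average",
    "compute_cell_averages",
    "degradation_face_rates",
]


@dataclass(frozen=True)
class BurstKernelCoefficients:
    """Per-dimension averaged burst coefficients (units 1/protein).

    ``beta_bar[d-1]`` is the interior-receiver coefficient at offset
    ``d = receiver - source >= 1``; ``tail[d-1]`` the boundary-receiver
    coefficient when the receiver is the last cell; ``self_coef`` the
    (negative) own-cell coefficient of interior sources.  The last cell's
    own coefficient is 0 (a burst from the saturated cell stays in place).
    """

    dim: int
    h: float
    b: float
    N: int
    self_coef: float
    beta_bar: np.ndarray
    tail: np.ndarray

    def column_sum(self, source: int) -> float:
        """Weighted column sum over receivers for a 1-based source cell.

        Weights are h/2 on the self term and h on every other receiver;
        zero (to machine precision) for every source by construction.
        """
        j, N, h = source, self.N, self.h
        if j == N:
            return 0.5 * h * 0.0
        d_int = np.arange(1, N - j)  # interior receivers j+1 .. N-1
        s = 0.5 * h * self.self_coef + h * self.beta_bar[d_int - 1].sum()
        s += h * self.tail[N - j - 1]
        return float(s)


def burst_coefficients(grid: TruncatedGrid, model: GRNModel, dim: int) -> BurstKernelCoefficients:
    """Averaged beta-kernel coefficients along ``dim`` (0-based).

    self term (interior source):  -(2/h) exp(-h / (2b))
    offset d >= 1 (interior receiver):
        (1/h) [exp(-(d-1/2) h / b) - exp(-(d+1/2) h / b)]
    boundary receiver (last cell), offset d >= 1:
        (1/h) exp(-(d-1/2) h / b)   — the full upper tail of omega.
    """
    h = grid.h[dim]
    b = model.burst[dim]
    N = grid.N[dim]
    if b <= 0:
        raise ValueError(f"burst size must be positive, got {b}")
    d = np.arange(1, N, dtype=float)
    lo = np.exp(-(d - 0.5) * h / b)
    hi = np.exp(-(d + 0.5) * h / b)
    return BurstKernelCoefficients(
        dim=dim,
        h=h,
        b=b,
        N=N,
        self_coef=-(2.0 / h) * np.exp(-h / (2.0 * b)),
        beta_bar=(lo - hi) / h,
        tail=lo / h,
    )


def _gauss_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights rescaled to the unit interval [0, 1].

    Weights are renormalized to sum to exactly 1 so constants average
    exactly (the raw weights carry O(eps) rounding).
    """
    x, w = np.polynomial.legendre.leggauss(order)
    w = w / w.sum()
    return 0.5 * (x + 1.0), w


def cell_average(
    grid: TruncatedGrid,
    f: Callable[[np.ndarray], np.ndarray],
    alpha: Sequence[int],
    order: int = 1,
) -> float:
    """Approximate (1/|K_alpha|) * integral of ``f`` over cell ``K_alpha``.

    ``order`` = 1 returns the midpoint value; ``order`` >= 2 a tensor-product
    Gauss-Legendre rule with ``order`` points per dimension (exact for
    polynomials up to degree 2*order - 1, and exact for constants at any
    order).  ``f`` maps points of shape (..., n) to values of shape (...).
    """
    lower, mid, _ = grid.cell_geometry(alpha)
    if order <= 1:
        val = float(np.asarray(f(np.asarray(mid)[None, :]))[0])
    else:
        nodes, weights = _gauss_nodes(order)
        h = np.asarray(grid.h)
        pts = np.stack(
            [lo + h_i * g for lo, h_i, g in zip(lower, h, np.meshgrid(*([nodes] * grid.n), indexing="ij"))],
            axis=-1,
        ).reshape(-1, grid.n)
        wts = np.prod(
            np.stack(np.meshgrid(*([weights] * grid.n), indexing="ij"), axis=-1).reshape(-1, grid.n),
            axis=1,
        )
        val = float(np.sum(wts * np.asarray(f(pts))))
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite cell average in cell {tuple(alpha)}")
    return val


@dataclass(frozen=True)
class CellAverages:
    """Flat-ordered cell averages of gamma_i and c_i for every gene i."""

    gamma: np.ndarray  # shape (n_genes, n_cells)
    c: np.ndarray  # shape (n_genes, n_cells)
    order: int

    def __post_init__(self):
        if np.any(self.c <= 0):
            raise ValueError("regulation averages must be strictly positive")
        if np.any(self.gamma <= 0):
            raise ValueError("degradation averages must be strictly positive")


def compute_cell_averages(grid: TruncatedGrid, model: GRNModel, order: int = 1) -> CellAverages:
    """Cell averages of every gamma_i and c_i over every grid cell.

    Vectorized over the whole grid: the quadrature is the same tensor rule
    as :func:`cell_average` applied with shared nodes across cells.
    """
    n, size = grid.n, grid.size
    gamma = np.empty((n, size))
    c = np.empty((n, size))
    if order <= 1:
        pts = grid.midpoint_array()
        for i in range(n):
            gamma[i] = eval_degradation(model, i, pts)
            c[i] = eval_regulation(model, i, pts)
    else:
        nodes, weights = _gauss_nodes(order)
        lower = grid.midpoint_array() - 0.5 * np.asarray(grid.h)
        gamma[:] = 0.0
        c[:] = 0.0
        for combo in itertools.product(range(order), repeat=n):
            offs = np.array([nodes[k] for k in combo]) * np.asarray(grid.h)
            wt = float(np.prod([weights[k] for k in combo]))
            pts = lower + offs
            for i in range(n):
                gamma[i] += wt * eval_degradation(model, i, pts)
                c[i] += wt * eval_regulation(model, i, pts)
    return CellAverages(gamma=gamma, c=c, order=order)


def degradation_face_rates(
    grid: TruncatedGrid, averages: CellAverages, dim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell degradation outflow and inflow rates along ``dim`` (1/time).

    outflow[alpha] = (1/h_i) * gamma_alpha^i * x_alpha^{i-1/2}: the rate at
    which cell alpha's mass moves to alpha - e_i (zero on the first layer,
    whose lower face sits at the origin).  inflow[alpha] is the same rate of
    the upper neighbour alpha + e_i (zero on the last layer).
    """
    h_i = grid.h[dim]
    shape = grid.N
    lower = grid.lower_faces_1d(dim)  # (alpha_i - 1) * h_i
    face = np.reshape(lower, [-1 if k == dim else 1 for k in range(grid.n)])
    gamma = averages.gamma[dim].reshape(shape)
    out = (gamma * face / h_i).ravel(order="C")
    out_nd = out.reshape(shape)
    inflow_nd = np.zeros_like(out_nd)
    src = [slice(None)] * grid.n
    dst = [slice(None)] * grid.n
    src[dim] = slice(1, None)
    dst[dim] = slice(0, -1)
    inflow_nd[tuple(dst)] = out_nd[tuple(src)]
    return out, inflow_nd.ravel(order="C")
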