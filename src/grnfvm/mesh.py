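"""Tensor-product finite-volume grid over a truncated protein-count domain.

The domain is [0, L_1) x ... x [0, L_n), divided into N_i equidistant cells
per dimension.  Cell multi-indices are 1-based (alpha_i = 1..N_i) to match
the usual finite-volume notation; flat indices are 0-based and lexicographic
with the *last* dimension varying fastest, so exported matrices are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TruncatedGrid"]


@dataclass(frozen=True)
class TruncatedGrid:
    """Equidistant tensor-product grid on [0, L_1) x ... x [0, L_n).

    Parameters
    ----------
    N : per-dimension cell counts (each >= 1).
    L : per-dimension domain lengths (protein units, > 0).

    Cell ``K_alpha`` spans ``[(alpha_i - 1) h_i, alpha_i h_i)`` in dimension
    ``i`` with width ``h_i = L_i / N_i``; its midpoint is
    ``(alpha_i - 1/2) h_i``.
    """

    N: tuple[int, ...]
    L: tuple[float, ...]

    def __init__(self, N: Sequence[int], L: Sequence[float]):
        N = tuple(int(v) for v in np.atleast_1d(N))
        L = tuple(float(v) for v in np.atleast_1d(L))
        if len(N) != len(L):
            raise ValueError(f"N and L must have equal length, got {len(N)} and {len(L)}")
        if len(N) == 0:
            raise ValueError("grid needs at least one dimension")
        if any(v < 1 for v in N):
            raise ValueError(f"cell counts must be >= 1, got N={N}")
        if any(v <= 0 for v in L):
            raise ValueError(f"domain lengths must be positive, got L={L}")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "L", L)

    @property
    def n(self) -> int:
        """Number of dimensions (genes)."""
        return len(self.N)

    @property
    def h(self) -> tuple[float, ...]:
        """Per-dimension cell widths h_i = L_i / N_i."""
        return tuple(Li / Ni for Li, Ni in zip(self.L, self.N))

    @property
    def cell_volume(self) -> float:
        """Volume h = prod(h_i) of a single cell."""
        return float(np.prod(self.h))

    @property
    def size(self) -> int:
        """Total number of cells N = prod(N_i)."""
        return int(np.prod(self.N))

    # ------------------------------------------------------------------ #
    # index arithmetic
    # ------------------------------------------------------------------ #
    def flat_index(self, alpha: Sequence[int]) -> int:
        """Map a 1-based multi-index to the 0-based flat index.

        Lexicographic, last dimension fastest (C order).
        """
        a = np.asarray(alpha, dtype=np.intp)
        if a.shape != (self.n,):
            raise IndexError(f"multi-index must have length {self.n}, got {a.shape}")
        if np.any(a < 1) or np.any(a > np.asarray(self.N)):
            raise IndexError(f"multi-index {tuple(a)} out of range for N={self.N}")
        return int(np.ravel_multi_index(a - 1, self.N, order="C"))

    def unflat_index(self, k: int) -> tuple[int, ...]:
        """Inverse of :meth:`flat_index`."""
        if not 0 <= k < self.size:
            raise IndexError(f"flat index {k} out of range [0, {self.size})")
        a = np.unravel_index(int(k), self.N, order="C")
        return tuple(int(v) + 1 for v in a)

    def cell_geometry(
        self, alpha: Sequence[int]
    ) -> tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]:
        """Lower faces, midpoint and upper faces of cell ``K_alpha``."""
        a = np.asarray(alpha, dtype=np.intp)
        self.flat_index(a)  # validates range
        h = np.asarray(self.h)
        lower = (a - 1) * h
        upper = a * h
        mid = (a - 0.5) * h
        return tuple(lower), tuple(mid), tuple(upper)

    # ------------------------------------------------------------------ #
    # bulk coordinates
    # ------------------------------------------------------------------ #
    def midpoints_1d(self, dim: int) -> np.ndarray:
        """Cell midpoints along one dimension, shape (N_dim,)."""
        h = self.h[dim]
        return (np.arange(1, self.N[dim] + 1) - 0.5) * h

    def midpoint_array(self) -> np.ndarray:
        """Midpoints of all cells in flat order, shape (size, n)."""
        axes = [self.midpoints_1d(i) for i in range(self.n)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel(order="C") for m in mesh], axis=-1)

    def lower_faces_1d(self, dim: int) -> np.ndarray:
        """Lower-face coordinates (alpha_i - 1) h_i along one dimension."""
        return np.arange(self.N[dim]) * self.h[dim]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TruncatedGrid(N={self.N}, L={self.L})"
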