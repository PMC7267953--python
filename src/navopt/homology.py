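"""Betti-0 persistence scoring of predicted functional matrices.

A weighted symmetric matrix is thresholded at every edge density
λ ∈ [0, 1]: keep the ⌊λ·E⌋ strongest off-diagonal entries (E = n(n−1)/2)
and count connected components β0(λ).  Real and predicted matrices are
compared by

    SSE_β = (1/n²) ∫₀¹ (β0(λ) − β̂0(λ))² dλ,

smaller is better.  Because the construction is rank-based, the score is
invariant under common strictly-monotone transforms of both matrices'
weights.  Edges are ranked by signed weight descending by default
(strongest positive correlations first); ``absolute=True`` ranks by
magnitude.  Ties break by (i, j) index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BettiCurve", "betti0_curve", "sse_beta"]


@dataclass
class BettiCurve:
    """β0 as a function of edge density; β0(0) = n, non-increasing, ≥ 1."""

    densities: np.ndarray
    beta0: np.ndarray

    @property
    def n(self) -> int:
        return int(self.beta0[0])


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            self.n_components -= 1


def _ranked_edges(M: np.ndarray, absolute: bool) -> tuple:
    n = M.shape[0]
    iu = np.triu_indices(n, k=1)
    w = M[iu]
    key = np.abs(w) if absolute else w
    # stable sort on -key keeps (i, j) lexicographic order among ties
    order = np.argsort(-key, kind="stable")
    return iu[0][order], iu[1][order]


def _beta0_by_rank(M: np.ndarray, absolute: bool) -> np.ndarray:
    """β0 after adding the j strongest edges, j = 0..E (incremental)."""
    n = M.shape[0]
    ii, jj = _ranked_edges(M, absolute)
    uf = _UnionFind(n)
    counts = np.empty(len(ii) + 1, dtype=int)
    counts[0] = n
    for k, (a, b) in enumerate(zip(ii, jj), start=1):
        uf.union(int(a), int(b))
        counts[k] = uf.n_components
    return counts


def betti0_curve(
    M: np.ndarray, grid: np.ndarray | None = None, absolute: bool = False
) -> BettiCurve:
    """Connected-component count across edge densities.

    ``grid`` defaults to one density step per edge rank (j/E for
    j = 0..E), which represents the piecewise-constant curve exactly;
    a coarser increasing grid in [0, 1] may be supplied for speed.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    E = n * (n - 1) // 2
    counts = _beta0_by_rank(M, absolute)
    if grid is None:
        grid = np.arange(E + 1) / E
    else:
        grid = np.asarray(grid, dtype=float)
    kept = np.floor(grid * E + 1e-9).astype(int)
    return BettiCurve(densities=grid, beta0=counts[kept])


def sse_beta(
    F_real: np.ndarray,
    F_pred: np.ndarray,
    grid: np.ndarray | None = None,
    absolute: bool = False,
) -> float:
    """Betti-0 goodness-of-fit: (1/n²) ∫ (β0 − β̂0)² dλ, trapezoidal.

    Zero iff the two curves agree on the grid; symmetric in its
    arguments.
    """
    F_real = np.asarray(F_real, dtype=float)
    F_pred = np.asarray(F_pred, dtype=float)
    if F_real.shape != F_pred.shape:
        raise ValueError("matrices must share dimensions")
    n = F_real.shape[0]
    c_real = betti0_curve(F_real, grid=grid, absolute=absolute)
    c_pred = betti0_curve(F_pred, grid=grid, absolute=absolute)
    diff2 = (c_real.beta0.astype(float) - c_pred.beta0.astype(float)) ** 2
    return float(np.trapezoid(diff2, c_real.densities) / n**2)
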