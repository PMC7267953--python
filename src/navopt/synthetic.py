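"""Synthetic connectome cohorts with planted ground truth.

Every input the analysis pipeline consumes can be generated here: 3-D
node layouts, structural networks built around a navigable game-optimal
core (plus planted long-range "nonoptimal" edges and dropped edges that
become false positives), functional matrices from the rotated-polynomial
forward model, rest/task functional pairs with a planted optimal/
nonoptimal dissociation, gene-expression matrices with a planted
component linear in regional optimality, and node partitions.

These generators define the study conditions of the synthetic
experiments; all are deterministic under a fixed seed.  They make no
attempt to mimic MRI noise physics, tractography biases or real gene
co-expression structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import euclidean_distance_matrix
from .nng import NNGNetwork, build_nng

__all__ = [
    "PlantedStructural",
    "DEFAULT_COEFFS",
    "gen_coords",
    "gen_structural",
    "gen_functional",
    "gen_rest_task_pair",
    "gen_expression",
    "gen_partition",
]

# Default forward-model coefficients (order k = 5).  The polynomial
# p(x) = x + 0.05x^2 + 0.3x^3 + 0.1x^5 has p'(x) = 1 + 0.1x + 0.9x^2 +
# 0.5x^4 > 0 everywhere, so p is strictly increasing on any spectrum:
# sorted-descending eigenvalue pairing between S and p(S) is then the
# identity and the planted map is identifiable by the spectral fit.
DEFAULT_COEFFS = (0.0, 1.0, 0.05, 0.3, 0.0, 0.1)

_MIN_WEIGHT = 1e-3
_WEIGHT_NOISE = 0.05


@dataclass
class PlantedStructural:
    """A structural network seeded from a known game equilibrium.

    ``labels`` tags every present edge as 'optimal' (kept NNG edge) or
    'nonoptimal' (planted extra edge); ``dropped`` lists the NNG edges
    removed from the structural matrix (downstream these are classified
    as false positives).
    """

    structural: np.ndarray
    labels: dict
    nng_truth: NNGNetwork
    dropped: set = field(default_factory=set)

    @property
    def optimal_edges(self) -> set:
        return {e for e, tag in self.labels.items() if tag == "optimal"}

    @property
    def nonoptimal_edges(self) -> set:
        return {e for e, tag in self.labels.items() if tag == "nonoptimal"}

    def masked(self, which: str) -> np.ndarray:
        """Structural matrix restricted to one edge class."""
        n = self.structural.shape[0]
        out = np.zeros_like(self.structural)
        edges = (self.optimal_edges if which == "optimal"
                 else self.nonoptimal_edges if which == "nonoptimal"
                 else None)
        if edges is None:
            if which != "all":
                raise ValueError(f"unknown edge class {which!r}")
            return self.structural.copy()
        for i, j in edges:
            out[i, j] = out[j, i] = self.structural[i, j]
        return out


def gen_coords(
    n: int, seed: int, layout: str = "uniform_box"
) -> np.ndarray:
    """Distinct 3-D node centroids.

    ``uniform_box``: uniform in a 100-unit cube.  ``two_blobs``: two
    Gaussian clusters (sd 10) around opposite centers, ⌈n/2⌉ + ⌊n/2⌋
    points.  Coincident points are resampled (bounded retries).
    """
    if n < 4:
        raise ValueError("need at least 4 nodes")
    rng = np.random.default_rng(seed)
    if layout == "uniform_box":
        pts = rng.uniform(0.0, 100.0, size=(n, 3))
    elif layout == "two_blobs":
        centers = np.array([[25.0, 50.0, 50.0], [75.0, 50.0, 50.0]])
        half = n // 2
        owner = np.repeat([0, 1], [n - half, half])
        pts = centers[owner] + rng.normal(0.0, 10.0, size=(n, 3))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    for _ in range(100):
        D = euclidean_distance_matrix(pts)
        np.fill_diagonal(D, np.inf)
        bad = np.unique(np.nonzero(D < 1e-9)[0])
        if bad.size == 0:
            return pts
        pts[bad] += rng.normal(0.0, 1e-3, size=(bad.size, 3))
    raise RuntimeError("could not separate coincident points")


def _edge_weights(dists: np.ndarray, d0: float, rng) -> np.ndarray:
    # GFA-like bounded weights, decreasing with distance plus positive noise
    w = np.exp(-dists / d0) + rng.uniform(0.0, _WEIGHT_NOISE, size=len(dists))
    return np.clip(w, _MIN_WEIGHT, 1.0)


def gen_structural(
    coords: np.ndarray,
    p_extra: float = 0.3,
    p_drop: float = 0.1,
    seed: int = 0,
) -> PlantedStructural:
    """Structural network = game-optimal core ± planted perturbations.

    The navigation-game equilibrium over ``coords`` seeds the edge set;
    each core edge is dropped independently with probability ``p_drop``
    (creating future false positives) and ⌈p_extra·m⌉ extra non-core
    edges are added, sampled with probability proportional to distance
    (long-range bias), becoming the planted nonoptimal class.  Weights
    decrease with distance and lie in (0, 1].
    """
    if not (0 <= p_extra < 1 and 0 <= p_drop < 1):
        raise ValueError("p_extra and p_drop must lie in [0, 1)")
    coords = np.asarray(coords, dtype=float)
    D = euclidean_distance_matrix(coords)
    rng = np.random.default_rng(seed)
    nng = build_nng(D)
    n = D.shape[0]
    core = sorted(nng.edge_set())
    keep = rng.random(len(core)) >= p_drop
    kept = [e for e, k in zip(core, keep) if k]
    dropped = {e for e, k in zip(core, keep) if not k}

    iu = np.triu_indices(n, k=1)
    all_pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    non_core = [e for e in all_pairs if e not in set(core)]
    n_extra = min(int(np.ceil(p_extra * len(core))), len(non_core))
    if n_extra > 0:
        d_nc = np.array([D[e] for e in non_core])
        p = d_nc / d_nc.sum()  # long-range bias: probability ∝ distance
        idx = rng.choice(len(non_core), size=n_extra, replace=False, p=p)
        extras = [non_core[k] for k in idx]
    else:
        extras = []

    d0 = float(np.median(D[iu]))
    S = np.zeros((n, n))
    labels: dict = {}
    for edges, tag in ((kept, "optimal"), (extras, "nonoptimal")):
        if edges:
            dists = np.array([D[e] for e in edges])
            w = _edge_weights(dists, d0, rng)
            for (i, j), wij in zip(edges, w):
                S[i, j] = S[j, i] = wij
                labels[(i, j)] = tag
    return PlantedStructural(
        structural=S, labels=labels, nng_truth=nng, dropped=dropped
    )


def _matrix_polynomial(S: np.ndarray, a) -> np.ndarray:
    n = S.shape[0]
    P = np.eye(n) * a[-1]
    for c in a[-2::-1]:
        P = P @ S + c * np.eye(n)
    return P


def random_rotation(n: int, seed: int) -> np.ndarray:
    """Haar-ish random special-orthogonal matrix (det = +1)."""
    rng = np.random.default_rng(seed)
    Q, Rq = np.linalg.qr(rng.normal(size=(n, n)))
    Q = Q * np.sign(np.diag(Rq))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q


def _symmetric_noise(n: int, sd: float, rng) -> np.ndarray:
    N = np.zeros((n, n))
    iu = np.triu_indices(n)
    N[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return N + np.triu(N, 1).T


def gen_functional(
    S: np.ndarray,
    a=DEFAULT_COEFFS,
    rotation_mode: str = "identity",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Forward model: F = R(Σ a_r S^r)Rᵀ + symmetric Gaussian noise."""
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    a = np.asarray(a, dtype=float)
    if len(a) < 2:
        raise ValueError("need polynomial order k >= 1 (len(a) >= 2)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = S.shape[0]
    rng = np.random.default_rng(seed)
    if rotation_mode == "identity":
        R = np.eye(n)
    elif rotation_mode == "random":
        R = random_rotation(n, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown rotation_mode {rotation_mode!r}")
    F = R @ _matrix_polynomial(S, a) @ R.T
    if noise_sd > 0:
        F = F + _symmetric_noise(n, noise_sd, rng)
    return (F + F.T) / 2.0


# Planted rest/task contrast: rest connectivity arises from the optimal
# core alone; task connectivity from a mixture that up-weights the planted
# nonoptimal (long-range) edges.  Because edge weights decay with distance,
# the nonoptimal submatrix carries far less spectral energy than the core;
# it is rescaled to the core's Frobenius norm before the gains apply, so
# the planted task state genuinely shifts communication energy onto the
# long-range class regardless of how many extra edges were planted.
TASK_NONOPT_GAIN = 2.0
TASK_OPT_GAIN = 0.25


def gen_rest_task_pair(
    planted: PlantedStructural,
    a=DEFAULT_COEFFS,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Rest/task functional pair with a planted optimal↔nonoptimal shift.

    Rest is the forward model of the optimal-edges-only submatrix; task
    is the forward model of an energy-rebalanced mixture with nonoptimal
    weights up (×2 after norm matching) and optimal weights down (×0.25).
    Independent noise per condition.
    """
    if not planted.optimal_edges or not planted.nonoptimal_edges:
        raise ValueError("need at least one optimal and one nonoptimal edge")
    ss = np.random.SeedSequence(seed)
    s_rest, s_task = (int(c.generate_state(1)[0] % 2**31)
                      for c in ss.spawn(2))
    S_rest = planted.masked("optimal")
    S_non = planted.masked("nonoptimal")
    S_non = S_non * (np.linalg.norm(S_rest) / np.linalg.norm(S_non))
    S_task = TASK_OPT_GAIN * S_rest + TASK_NONOPT_GAIN * S_non
    rest = gen_functional(S_rest, a=a, rotation_mode="identity",
                          noise_sd=noise_sd, seed=s_rest)
    task = gen_functional(S_task, a=a, rotation_mode="identity",
                          noise_sd=noise_sd, seed=s_task)
    return rest, task


EXPRESSION_ALPHA = 1.0


def gen_expression(
    ro: np.ndarray,
    n_genes: int = 100,
    n_signal: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """ROI×gene expression with a planted component linear in RO.

    ``n_signal`` gene columns equal α·ro + Gaussian noise (α = 1);
    the rest are pure standard-normal noise.  Signal genes are named
    ``gene_s###`` and noise genes ``gene_n###`` (ground truth is carried
    in the names); the column order is shuffled under the seed.
    """
    ro = np.asarray(ro, dtype=float).ravel()
    if n_signal > n_genes:
        raise ValueError("n_signal must be <= n_genes")
    rng = np.random.default_rng(seed)
    n = len(ro)
    cols, names = [], []
    for g in range(n_signal):
        cols.append(EXPRESSION_ALPHA * ro + rng.normal(0.0, noise_sd, n))
        names.append(f"gene_s{g:04d}")
    for g in range(n_genes - n_signal):
        cols.append(rng.normal(0.0, 1.0, n))
        names.append(f"gene_n{g:04d}")
    X = pd.DataFrame(np.column_stack(cols) if cols else np.empty((n, 0)),
                     columns=names)
    perm = rng.permutation(n_genes)
    return X.iloc[:, perm]


def gen_partition(n: int, k_networks: int, seed: int = 0) -> np.ndarray:
    """Random node→network labels, every label used at least once."""
    if not 1 <= k_networks <= n:
        raise ValueError("need 1 <= k_networks <= n")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([
        np.arange(k_networks),
        rng.integers(0, k_networks, size=n - k_networks),
    ])
    rng.shuffle(labels)
    return np.array([f"net{v}" for v in labels])
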