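"""Nash-equilibrium network game (NNG) model of optimal connectomes.

Every node, placed in space, plays the same game: connect to as few
neighbours as possible while still being able to *navigate* (greedy-route)
information to every other node.  The set of targets reachable from ``u``
through a first hop ``v`` is the navigation set

    S_v^u = { w : dist(v, w) < dist(u, w) },

and the node's optimal strategy is a minimum set cover of the target
universe by the S_v^u.  Pooling every node's optimal strategy yields the
Nash-equilibrium network: maximally navigable with a minimum number of
edges.  Overlaying this synthetic optimum on a measured structural network
classifies each structural edge as *optimal* (present in both), or
*nonoptimal* (structural only); NNG edges missing from the structural
network are *false positives*, and the optimality score is |T|/|M|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .distances import validate_distance_matrix

__all__ = [
    "NNGNetwork",
    "EdgeClassification",
    "navigation_set",
    "navigation_set_matrix",
    "optimal_navigation_vector",
    "build_nng",
    "greedy_route",
    "navigability",
    "classify_edges",
]


# --------------------------------------------------------------------------
# data containers


@dataclass
class NNGNetwork:
    """Result of the network formation game.

    Attributes
    ----------
    adjacency : (n, n) int ndarray
        Binary symmetric adjacency: the union of every node's chosen
        connections, symmetrized (an edge appears if either endpoint
        chose the other).
    chosen : list[frozenset[int]]
        Per-node optimal navigation vector: the neighbours each node
        selected in its minimum cover.
    """

    adjacency: np.ndarray
    chosen: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """|M|: number of undirected NNG edges."""
        return int(np.triu(self.adjacency, 1).sum())

    def edge_set(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class EdgeClassification:
    """Partition of the edge universe against the game-optimal network.

    ``optimal`` (T) are edges present in both the structural network and
    the NNG; ``nonoptimal`` are structural-only; ``false_positive`` (F)
    are NNG-only.  |T| + |F| = |M| and optimality = |T|/|M|.
    """

    optimal: set
    nonoptimal: set
    false_positive: set
    n_nng_edges: int

    @property
    def optimality(self) -> float:
        if self.n_nng_edges == 0:
            return float("nan")
        return len(self.optimal) / self.n_nng_edges

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positive)

    def mask(self, which: str, n: int) -> np.ndarray:
        """Boolean (n, n) symmetric mask selecting one edge class.

        ``which`` is one of ``optimal``, ``nonoptimal``, ``all`` ("all"
        means every real structural edge, i.e. optimal ∪ nonoptimal;
        false positives do not exist in the real network).
        """
        if which == "all":
            edges = self.optimal | self.nonoptimal
        elif which == "optimal":
            edges = self.optimal
        elif which == "nonoptimal":
            edges = self.nonoptimal
        else:
            raise ValueError(f"unknown edge class {which!r}")
        m = np.zeros((n, n), dtype=bool)
        for i, j in edges:
            m[i, j] = m[j, i] = True
        return m


# --------------------------------------------------------------------------
# navigation sets


def navigation_set(u: int, v: int, D: np.ndarray) -> set:
    """Targets reachable from ``u`` using ``v`` as the greedy first hop.

    S_v^u = {w != u : D(v, w) < D(u, w)} with strict inequality.  ``v``
    itself is always a member (D(v, v) = 0 < D(u, v)) and ``u`` never is.
    """
    if u == v:
        raise ValueError("u and v must be distinct")
    D = np.asarray(D, dtype=float)
    members = np.nonzero(D[v] < D[u])[0]
    return set(int(w) for w in members if w != u)


def navigation_set_matrix(u: int, D: np.ndarray) -> np.ndarray:
    """All navigation sets of node ``u`` at once.

    Returns a boolean (n, n) matrix B with B[v, w] True iff w ∈ S_v^u.
    Row ``u`` and column ``u`` are all False.
    """
    D = np.asarray(D, dtype=float)
    B = D < D[u][None, :]
    B[u, :] = False
    B[:, u] = False
    return B


# --------------------------------------------------------------------------
# exact minimum set cover

# Tie-break: among minimum covers, prefer the lexicographically smallest
# index set.  Encoded as cost 1 - 2^{-(v+2)} per candidate v, so the solver
# maximizes sum(2^{-v}) at fixed cardinality; the total perturbation is
# < 1/2 and cannot change the cardinality optimum.  Below double precision
# (index ≳ 45) the perturbation vanishes and the (deterministic) solver's
# own tie-break applies.
_TIE_EPS_LIMIT = 60


def _lex_costs(candidates: np.ndarray) -> np.ndarray:
    ranks = np.argsort(np.argsort(candidates))
    return 1.0 - np.power(2.0, -(np.minimum(ranks, _TIE_EPS_LIMIT) + 2.0))


def _cover_milp(sets: np.ndarray, candidates: np.ndarray) -> list:
    # sets[k] is the boolean membership row of candidate k over the universe
    n_sets, n_elem = sets.shape
    A = sets.T.astype(float)  # constraints: each element covered >= once
    res = milp(
        c=_lex_costs(candidates),
        constraints=LinearConstraint(A, lb=np.ones(n_elem), ub=np.inf),
        integrality=np.ones(n_sets),
        bounds=(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if not res.success:  # pragma: no cover - infeasibility is impossible here
        raise RuntimeError(f"set-cover ILP failed: {res.message}")
    return [int(c) for c, x in zip(candidates, res.x) if x > 0.5]


def _cover_brute(sets: np.ndarray, candidates: np.ndarray) -> list:
    n_sets, n_elem = sets.shape
    full = np.ones(n_elem, dtype=bool)
    order = np.argsort(candidates)
    for size in range(1, n_sets + 1):
        # combinations over index-sorted candidates yield lexicographic
        # order, so the first cover found is the lexicographically smallest
        # among minimum covers
        for combo in itertools.combinations(order, size):
            if np.all(sets[list(combo)].any(axis=0) == full):
                return sorted(int(candidates[k]) for k in combo)
    raise RuntimeError("no cover exists")  # pragma: no cover


def optimal_navigation_vector(
    u: int, D: np.ndarray, method: str = "auto"
) -> frozenset:
    """Exact minimum-cardinality greedy-navigation strategy of node ``u``.

    Selects the smallest set of first-hop neighbours v whose navigation
    sets S_v^u jointly cover every other node.  The cover is exact (not
    greedy-approximate): integer programming via HiGHS, or exhaustive
    enumeration (``method='brute'``, used automatically for tiny n).

    Feasibility is guaranteed because every target w lies in its own set
    S_w^u.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    B = navigation_set_matrix(u, D)
    candidates = np.array([v for v in range(n) if v != u])
    universe = candidates  # targets: all nodes except u
    sets = B[np.ix_(candidates, universe)]
    if method == "auto":
        method = "brute" if n <= 6 else "milp"
    if method == "brute":
        chosen = _cover_brute(sets, candidates)
    elif method == "milp":
        chosen = _cover_milp(sets, candidates)
    else:
        raise ValueError(f"unknown method {method!r}")
    return frozenset(chosen)


# --------------------------------------------------------------------------
# game equilibrium


def build_nng(
    D: np.ndarray,
    method: str = "auto",
    blocks: np.ndarray | None = None,
) -> NNGNetwork:
    """Play the navigation game for every node and pool the equilibrium.

    Parameters
    ----------
    D : (n, n) distance matrix (validated).
    method : 'auto' | 'milp' | 'brute' — set-cover solver.
    blocks : optional per-node block labels (e.g. hemispheres).  When
        given, the game is played separately inside each block (as when
        geodesic distances are only defined within a hemisphere) and the
        block equilibria are pooled into one block-diagonal network.

    Returns
    -------
    NNGNetwork with the symmetrized union of every node's chosen set.
    """
    D = validate_distance_matrix(D)
    n = D.shape[0]
    if n == 1:
        return NNGNetwork(adjacency=np.zeros((1, 1), dtype=int),
                          chosen=[frozenset()])
    if blocks is not None:
        blocks = np.asarray(blocks)
        adjacency = np.zeros((n, n), dtype=int)
        chosen: list = [frozenset()] * n
        for label in np.unique(blocks):
            idx = np.nonzero(blocks == label)[0]
            sub = build_nng(D[np.ix_(idx, idx)], method=method)
            adjacency[np.ix_(idx, idx)] = sub.adjacency
            for local, node in enumerate(idx):
                chosen[node] = frozenset(int(idx[v]) for v in sub.chosen[local])
        return NNGNetwork(adjacency=adjacency, chosen=chosen)

    chosen = [optimal_navigation_vector(u, D, method=method) for u in range(n)]
    adjacency = np.zeros((n, n), dtype=int)
    for u, C in enumerate(chosen):
        for v in C:
            adjacency[u, v] = adjacency[v, u] = 1
    return NNGNetwork(adjacency=adjacency, chosen=chosen)


# --------------------------------------------------------------------------
# greedy routing


def greedy_route(adj: np.ndarray, D: np.ndarray, s: int, t: int):
    """Hop-by-hop navigation from ``s`` to ``t``.

    At each step move to the neighbour closest to the target; fail (return
    None) when no neighbour is strictly closer than the current node,
    which also guarantees termination.  Ties resolve to the lowest node
    index.
    """
    if s == t:
        raise ValueError("source and target must differ")
    adj = np.asarray(adj)
    D = np.asarray(D, dtype=float)
    path = [s]
    current = s
    while current != t:
        nbrs = np.nonzero(adj[current])[0]
        if nbrs.size == 0:
            return None
        best = nbrs[np.argmin(D[nbrs, t])]
        if D[best, t] >= D[current, t]:
            return None
        path.append(int(best))
        current = int(best)
    return path


def navigability(adj: np.ndarray, D: np.ndarray) -> float:
    """Fraction of ordered node pairs with a successful greedy route."""
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    ok = 0
    for s in range(n):
        for t in range(n):
            if s != t and greedy_route(adj, D, s, t) is not None:
                ok += 1
    return ok / (n * (n - 1))


# --------------------------------------------------------------------------
# edge classification


def classify_edges(S: np.ndarray, nng: NNGNetwork) -> EdgeClassification:
    """Overlay a structural network on the game equilibrium.

    A structural edge exists wherever the weight is nonzero (GFA or
    streamline count).  Optimal = structural ∩ NNG; nonoptimal =
    structural \\ NNG; false positive = NNG \\ structural.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != nng.adjacency.shape:
        raise ValueError("structural matrix and NNG dimensions differ")
    iu = np.triu_indices(S.shape[0], k=1)
    s_edges = {(int(i), int(j)) for i, j in zip(*iu) if S[i, j] != 0}
    m_edges = nng.edge_set()
    return EdgeClassification(
        optimal=s_edges & m_edges,
        nonoptimal=s_edges - m_edges,
        false_positive=m_edges - s_edges,
        n_nng_edges=len(m_edges),
    )
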