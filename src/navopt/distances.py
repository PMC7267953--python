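"""Inter-node distance matrices.

The navigation game consumes nothing but a symmetric, zero-diagonal,
strictly-positive-off-diagonal distance matrix.  By default it is the
Euclidean distance between 3-D node centroids; any user-supplied matrix
(e.g. geodesic distances along a cortical surface, computed elsewhere)
is accepted as-is.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["euclidean_distance_matrix", "validate_distance_matrix"]


def euclidean_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between node coordinates.

    Parameters
    ----------
    coords : (n, 3) array_like
        One row of x, y, z coordinates per node.

    Returns
    -------
    (n, n) ndarray with zero diagonal.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be a 2-D (n, d) array")
    return squareform(pdist(coords))


def validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    """Check symmetry, zero diagonal and positive off-diagonal entries.

    Returns the validated matrix as a float ndarray; raises ``ValueError``
    on any violation (including duplicate points, which appear as zero
    off-diagonal distances and would break greedy navigation).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if np.any(off <= 0):
        raise ValueError(
            "off-diagonal distances must be strictly positive "
            "(duplicate node positions are not allowed)"
        )
    return D
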