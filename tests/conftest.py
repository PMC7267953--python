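import numpy as np
import pytest

from navopt.distances import euclidean_distance_matrix
from navopt.synthetic import gen_coords


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron: fully symmetric 4-point layout."""
    return np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ])


@pytest.fixture
def line_coords():
    """Three collinear points at x = 0, 1, 2."""
    return np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])


@pytest.fixture
def small_layout():
    """A generic 12-node random layout and its distance matrix."""
    coords = gen_coords(12, seed=99)
    return coords, euclidean_distance_matrix(coords)
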