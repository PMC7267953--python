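"""Synthetic generators: determinism, planted ground truth, forward model."""

import numpy as np
import pytest
from scipy import stats

from navopt.distances import euclidean_distance_matrix
from navopt.nng import build_nng, classify_edges
from navopt.spectral import fit_spectral_map
from navopt.synthetic import (
    DEFAULT_COEFFS,
    gen_coords,
    gen_expression,
    gen_functional,
    gen_partition,
    gen_rest_task_pair,
    gen_structural,
)


class TestGenCoords:
    def test_deterministic_and_distinct(self):
        a = gen_coords(4, seed=1)
        b = gen_coords(4, seed=1)
        np.testing.assert_array_equal(a, b)
        D = euclidean_distance_matrix(a)
        assert np.all(D[~np.eye(4, dtype=bool)] > 0)

    def test_two_blobs_clusters(self):
        # nearest-centroid audit: each half belongs to its own blob
        pts = gen_coords(50, seed=7, layout="two_blobs")
        centers = np.array([[25.0, 50, 50], [75.0, 50, 50]])
        d = np.linalg.norm(pts[:, None] - centers[None], axis=2)
        owner = d.argmin(axis=1)
        assert (owner == 0).sum() == 25
        assert (owner == 1).sum() == 25

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            gen_coords(3, seed=0)


class TestGenStructural:
    def test_no_perturbation_equals_nng(self):
        coords = gen_coords(15, seed=2)
        planted = gen_structural(coords, p_extra=0.0, p_drop=0.0, seed=3)
        assert planted.optimal_edges == planted.nng_truth.edge_set()
        assert not planted.nonoptimal_edges and not planted.dropped

    @pytest.mark.parametrize("seed", range(4))
    def test_roundtrip_label_recovery(self, seed):
        coords = gen_coords(18, seed=seed)
        planted = gen_structural(coords, p_extra=0.3, p_drop=0.0, seed=seed)
        D = euclidean_distance_matrix(coords)
        cls = classify_edges(planted.structural, build_nng(D))
        assert cls.optimal == planted.optimal_edges
        assert cls.nonoptimal == planted.nonoptimal_edges
        assert cls.n_false_positives == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_dropped_edges_become_false_positives(self, seed):
        coords = gen_coords(18, seed=seed + 40)
        planted = gen_structural(coords, p_extra=0.2, p_drop=0.25,
                                 seed=seed)
        D = euclidean_distance_matrix(coords)
        cls = classify_edges(planted.structural, build_nng(D))
        assert cls.false_positive == planted.dropped
        assert cls.n_false_positives == len(planted.dropped)

    def test_weights_bounded_and_invariants(self):
        coords = gen_coords(20, seed=5)
        planted = gen_structural(coords, p_extra=0.4, p_drop=0.1, seed=6)
        S = planted.structural
        w = S[S != 0]
        assert np.all((w > 0) & (w <= 1))
        truth = planted.nng_truth.edge_set()
        assert planted.optimal_edges <= truth
        assert not (planted.nonoptimal_edges & truth)

    def test_invalid_probabilities_rejected(self):
        coords = gen_coords(6, seed=0)
        with pytest.raises(ValueError):
            gen_structural(coords, p_extra=1.0, p_drop=0.0)


class TestGenFunctional:
    def test_identity_polynomial_returns_s(self, small_layout):
        _, D = small_layout
        S = np.exp(-D)
        np.fill_diagonal(S, 0.0)
        F = gen_functional(S, a=(0.0, 1.0), rotation_mode="identity",
                           noise_sd=0.0, seed=0)
        np.testing.assert_allclose(F, S, atol=1e-12)

    def test_square_polynomial(self, small_layout):
        _, D = small_layout
        S = np.exp(-D)
        np.fill_diagonal(S, 0.0)
        F = gen_functional(S, a=(0.0, 0.0, 1.0), rotation_mode="identity",
                           noise_sd=0.0, seed=0)
        np.testing.assert_allclose(F, S @ S, atol=1e-10)

    def test_rotation_preserves_spectrum(self, small_layout):
        _, D = small_layout
        S = np.exp(-D)
        np.fill_diagonal(S, 0.0)
        a = DEFAULT_COEFFS
        F = gen_functional(S, a=a, rotation_mode="random", noise_sd=0.0,
                           seed=4)
        P = gen_functional(S, a=a, rotation_mode="identity", noise_sd=0.0,
                           seed=4)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(F)),
            np.sort(np.linalg.eigvalsh(P)),
            atol=1e-10,
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            gen_functional(np.arange(9.0).reshape(3, 3))

    def test_default_polynomial_monotone_on_wide_range(self):
        # identifiability of the planted map requires the generating
        # polynomial to be strictly increasing, so sorted-eigenvalue
        # pairing is the identity
        x = np.linspace(-50, 50, 20001)
        p = np.polynomial.polynomial.polyval(x, DEFAULT_COEFFS)
        assert np.all(np.diff(p) > 0)


@pytest.fixture(scope="module")
def planted():
    coords = gen_coords(30, seed=31)
    return gen_structural(coords, p_extra=0.3, p_drop=0.1, seed=32)


class TestRestTaskPair:
    def test_noiseless_rest_recovered_from_optimal_mask(self, planted):
        rest, _ = gen_rest_task_pair(planted, noise_sd=0.0, seed=1)
        res = fit_spectral_map(planted.masked("optimal"), rest, k=5)
        assert res.score() >= 0.999

    def test_task_better_predicted_by_nonoptimal_mask(self, planted):
        _, task = gen_rest_task_pair(planted, noise_sd=0.0, seed=2)
        r_non = fit_spectral_map(planted.masked("nonoptimal"), task).score()
        r_opt = fit_spectral_map(planted.masked("optimal"), task).score()
        assert r_non > r_opt

    def test_deterministic_under_seed(self, planted):
        p1 = gen_rest_task_pair(planted, noise_sd=0.1, seed=3)
        p2 = gen_rest_task_pair(planted, noise_sd=0.1, seed=3)
        np.testing.assert_array_equal(p1[0], p2[0])
        np.testing.assert_array_equal(p1[1], p2[1])

    def test_empty_edge_class_rejected(self):
        coords = gen_coords(10, seed=33)
        no_extras = gen_structural(coords, p_extra=0.0, p_drop=0.0, seed=0)
        with pytest.raises(ValueError):
            gen_rest_task_pair(no_extras)


class TestGenExpression:
    def test_noiseless_signal_columns_track_ro(self):
        rng = np.random.default_rng(20)
        ro = rng.normal(size=40)
        X = gen_expression(ro, n_genes=30, n_signal=6, noise_sd=0.0, seed=21)
        for col in X.columns:
            if col.startswith("gene_s"):
                rho = stats.spearmanr(X[col], ro).statistic
                assert rho == pytest.approx(1.0)

    def test_byte_identical_under_seed(self):
        ro = np.random.default_rng(22).normal(size=20)
        a = gen_expression(ro, 40, 5, 0.5, seed=23)
        b = gen_expression(ro, 40, 5, 0.5, seed=23)
        assert a.equals(b)

    def test_signal_count_validation(self):
        ro = np.zeros(10)
        with pytest.raises(ValueError):
            gen_expression(ro, n_genes=5, n_signal=6)

    def test_column_composition(self):
        ro = np.random.default_rng(24).normal(size=15)
        X = gen_expression(ro, n_genes=50, n_signal=7, seed=25)
        assert sum(c.startswith("gene_s") for c in X.columns) == 7
        assert sum(c.startswith("gene_n") for c in X.columns) == 43


class TestGenPartition:
    def test_bijection_when_k_equals_n(self):
        labels = gen_partition(7, 7, seed=0)
        assert len(set(labels)) == 7

    def test_every_label_used_and_counts_sum(self):
        labels = gen_partition(50, 7, seed=1)
        assert len(labels) == 50
        assert len(set(labels)) == 7

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(
            gen_partition(10, 3, seed=4), gen_partition(10, 3, seed=4)
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            gen_partition(5, 6, seed=0)
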