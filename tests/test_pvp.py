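import numpy as np
import pytest

from protolex.pvp import (
    LinearDependenceError,
    l2_fit,
    l2_select_prototypes,
    nmf_project,
    orthonormalize,
    pvp_fit,
    pvp_project,
    pvp_score,
    select_prototypes,
    svd_project_nonneg,
)


def brute_force_selection(X, d):
    """Literal prototype selection: recompute the centroid of the remaining
    vectors each round and take the best pvp_score (ties -> lowest index)."""
    X = np.asarray(X, dtype=float)
    remaining = list(range(X.shape[0]))
    order = []
    for _ in range(d):
        centroid = X[remaining].mean(axis=0)
        scores = [pvp_score(X[i], centroid) for i in remaining]
        best = remaining[int(np.argmax(scores))]
        order.append(best)
        remaining.remove(best)
    return order


class TestScore:
    def test_manual_elementwise_product(self):
        assert pvp_score(np.array([1, 0, 2]), np.array([0, 1, 3])) == 1

    def test_disjoint_supports(self):
        assert pvp_score(np.array([1, 1, 0]), np.array([0, 0, 2])) == 0

    def test_full_overlap(self):
        assert pvp_score(np.ones(7), np.full(7, 0.5)) == 7

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pvp_score(np.ones(3), np.ones(4))


class TestSelection:
    def test_hand_trace(self):
        X = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        assert select_prototypes(X, 2) == [3, 0]

    def test_full_exhaustion_matches_brute_force(self, rng):
        X = rng.random((12, 6))
        X[rng.random((12, 6)) < 0.5] = 0
        n = X.shape[0]
        assert select_prototypes(X, n) == brute_force_selection(X, n)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_literal_algorithm_on_random_sparse(self, seed):
        r = np.random.default_rng(seed)
        X = r.random((20, 10))
        X[r.random((20, 10)) < 0.6] = 0
        assert select_prototypes(X, 8) == brute_force_selection(X, 8)

    def test_identical_rows_tie_to_lower_index(self):
        X = np.array([[1, 1], [1, 1], [1, 0]], dtype=float)
        assert select_prototypes(X, 2)[0] == 0

    def test_d_out_of_range(self):
        with pytest.raises(ValueError):
            select_prototypes(np.ones((3, 2)), 4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            select_prototypes(np.array([[1.0, -1.0]]), 1)


class TestOrthonormalize:
    def test_orthonormal_input_is_fixed_point(self):
        Q = np.eye(3)[[2, 0]]
        out = orthonormalize(Q)
        np.testing.assert_allclose(out, Q, atol=1e-12)

    def test_textbook_two_vector_case(self):
        out = orthonormalize([np.array([1.0, 0.0]), np.array([1.0, 1.0])])
        np.testing.assert_allclose(out, [[1, 0], [0, 1]], atol=1e-12)

    def test_collinear_input_signals_dependence(self):
        with pytest.raises(LinearDependenceError) as exc:
            orthonormalize([np.array([1.0, 0.0]), np.array([2.0, 0.0])])
        assert exc.value.index == 1

    def test_output_is_orthonormal(self, rng):
        V = rng.random((8, 20))
        Q = orthonormalize(V)
        np.testing.assert_allclose(Q @ Q.T, np.eye(8), atol=1e-8)


class TestFitAndProject:
    def test_dependent_prototype_replaced_by_next_best(self):
        # rows 0 and 1 are identical and maximal; fit must skip one
        X = np.array([[1, 1, 1], [1, 1, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="dependent"):
            basis = pvp_fit(X, 3)
        assert basis.indices[0] == 0
        assert 1 not in basis.indices
        assert basis.orthonormal_basis.shape == (3, 3)

    def test_canonical_basis_projection_selects_coordinates(self, rng):
        X = rng.random((5, 4))
        from protolex.pvp import PrototypeBasis

        basis = PrototypeBasis(
            selected_prototypes=np.eye(4)[:2],
            orthonormal_basis=np.eye(4)[:2],
            indices=(0, 1),
            source_dim=4,
            target_dim=2,
        )
        proj = pvp_project(X, basis)
        np.testing.assert_allclose(proj.values, X[:, :2], atol=1e-12)

    def test_orthogonal_row_projects_to_zero(self):
        X = np.array([[0.0, 0.0, 5.0]])
        basis = pvp_fit(np.array([[1.0, 0, 0], [0, 1.0, 0]]), 2)
        np.testing.assert_allclose(
            pvp_project(X, basis).values, [[0.0, 0.0]], atol=1e-12
        )

    def test_matches_dense_inner_product_oracle(self, rng):
        X = rng.random((20, 10))
        basis = pvp_fit(X, 6)
        proj = pvp_project(X, basis)
        oracle = np.array(
            [
                [x @ p for p in basis.orthonormal_basis]
                for x in X
            ]
        )
        np.testing.assert_allclose(proj.values, oracle, atol=1e-12)

    def test_projection_is_linear(self, rng):
        X = rng.random((6, 9))
        Y = rng.random((6, 9))
        basis = pvp_fit(np.abs(rng.random((9, 9))), 4)
        left = pvp_project(2.0 * X + 3.0 * Y, basis).values
        right = 2.0 * pvp_project(X, basis).values + 3.0 * pvp_project(Y, basis).values
        np.testing.assert_allclose(left, right, atol=1e-10)

    def test_raw_prototype_mode_keeps_projections_non_negative(self, synth_small):
        basis = pvp_fit(synth_small, 10)
        proj = pvp_project(synth_small, basis, raw_prototypes=True)
        assert proj.values.min() >= 0

    def test_dimension_mismatch(self, synth_small):
        basis = pvp_fit(synth_small, 5)
        with pytest.raises(ValueError, match="mismatch"):
            pvp_project(np.ones((2, 3)), basis)


class TestCentroidScoreBound:
    """The centroid score upper-bounds the average per-vector score for
    non-negative data, with equality when all vectors share one support
    (the general equality stated for this quantity does not hold:
    y=(1,1), x1=(1,0), x2=(0,1) gives average 1 but centroid score 2)."""

    def test_documented_counterexample(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1.0, 1.0])
        avg = np.mean([pvp_score(xi, y) for xi in x])
        centroid = pvp_score(x.mean(axis=0), y)
        assert avg == 1.0 and centroid == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_inequality_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        X = r.random((8, 12))
        X[r.random((8, 12)) < 0.5] = 0
        y = r.random(12)
        y[r.random(12) < 0.5] = 0
        avg = np.mean([pvp_score(xi, y) for xi in X])
        assert pvp_score(X.mean(axis=0), y) >= avg

    def test_equality_on_shared_support(self, rng):
        support = np.array([1, 0, 1, 1, 0], dtype=bool)
        X = rng.random((6, 5)) * support
        y = rng.random(5)
        y[0] = 0.0
        avg = np.mean([pvp_score(xi, y) for xi in X])
        assert pvp_score(X.mean(axis=0), y) == avg


class TestL2Baseline:
    def test_sorted_by_norm(self):
        X = np.diag([3.0, 2.0, 1.0])
        assert l2_select_prototypes(X, 2) == [0, 1]

    def test_equal_norms_tie_to_first_indices(self):
        X = np.eye(4)
        assert l2_select_prototypes(X, 3) == [0, 1, 2]

    def test_agreement_with_sorting_oracle(self, rng):
        X = rng.random((50, 30))
        got = l2_select_prototypes(X, 50)
        norms = np.linalg.norm(X, axis=1)
        oracle = sorted(range(50), key=lambda i: (-norms[i], i))
        assert got == oracle

    def test_l2_fit_produces_orthonormal_basis(self, synth_small):
        basis = l2_fit(synth_small, 8)
        Q = basis.orthonormal_basis
        np.testing.assert_allclose(Q @ Q.T, np.eye(8), atol=1e-8)


class TestSvdProjection:
    def test_output_non_negative(self, synth_small):
        assert svd_project_nonneg(synth_small, 10).values.min() >= 0

    def test_rank_one_matrix_projects_to_row_norms(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 0.5, 0.0, 0.0])
        X = np.outer(u, v)
        proj = svd_project_nonneg(X, 1).values.ravel()
        np.testing.assert_allclose(proj, np.linalg.norm(X, axis=1), atol=1e-10)

    def test_reconstruction_matches_eigendecomposition_oracle(self):
        X = np.array(
            [[1.0, 2.0, 0.0], [0.0, 1.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 1.0]]
        )
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :3] * S[:3]) @ Vt[:3]
        # oracle: eigendecomposition of the Gram matrix X'X
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        oracle = X @ evecs @ evecs.T
        np.testing.assert_allclose(recon, oracle, atol=1e-8)
        np.testing.assert_allclose(S**2, evals, atol=1e-8)

    def test_d_too_large_rejected(self):
        with pytest.raises(ValueError):
            svd_project_nonneg(np.ones((3, 2)), 3)


class TestNmfProjection:
    def test_factors_non_negative(self, synth_small):
        assert nmf_project(synth_small, 5, seed=0, max_iter=100).values.min() >= 0

    def test_planted_factorization_recovered(self, rng):
        W0 = rng.random((40, 4))
        H0 = rng.random((4, 15))
        X = W0 @ H0
        from sklearn.decomposition import NMF

        proj = nmf_project(X, 4, seed=0, max_iter=2000, tol=1e-8)
        model = NMF(
            n_components=4, solver="mu", init="random", random_state=0,
            max_iter=2000, tol=1e-8,
        )
        W = model.fit_transform(X)
        err = np.linalg.norm(X - W @ model.components_)
        assert err < 1e-3 * np.linalg.norm(X)
        np.testing.assert_allclose(proj.values, W, atol=1e-10)

    def test_more_iterations_never_increase_error(self, synth_small):
        from sklearn.decomposition import NMF

        X = synth_small.toarray()
        errs = []
        for it in (10, 50, 200):
            m = NMF(
                n_components=5, solver="mu", init="random", random_state=0,
                max_iter=it, tol=0.0,
            )
            m.fit(X)
            errs.append(m.reconstruction_err_)
        assert errs[0] >= errs[1] >= errs[2]

    def test_deterministic_under_seed(self, synth_small):
        a = nmf_project(synth_small, 5, seed=3, max_iter=50).values
        b = nmf_project(synth_small, 5, seed=3, max_iter=50).values
        np.testing.assert_array_equal(a, b)
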