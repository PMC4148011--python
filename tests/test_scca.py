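"""Sparse CCA fitting, penalty selection, bidirectional prediction."""

import numpy as np
import pytest

from conncca.connectome import devectorize, edge_index_for, EdgeDataset
from conncca.scca import (
    default_penalty_grid,
    predict_x_from_y,
    predict_y_from_x,
    scca_fit,
    select_penalties,
    soft_threshold,
)
from conncca.spd import check_spd
from conncca.synthetic import make_linked_edge_datasets


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "a, delta, expected",
        [
            ([2.0, -0.5, 3.0], 1.0, [1.0, 0.0, 2.0]),
            ([2.0, -0.5, 3.0], 0.0, [2.0, -0.5, 3.0]),
            ([2.0, -0.5, 3.0], 3.0, [0.0, 0.0, 0.0]),
        ],
    )
    def test_examples(self, a, delta, expected):
        np.testing.assert_allclose(soft_threshold(np.array(a), delta), expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


class TestSccaFit:
    def test_max_penalties_recover_leading_singular_pair(self, rng):
        for _ in range(5):
            X = rng.standard_normal((10, 8))
            Y = rng.standard_normal((10, 6))
            model = scca_fit(X, Y, np.sqrt(8), np.sqrt(6), K=1)
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            U, _, Vt = np.linalg.svd(Xc.T @ Yc)
            assert abs(U[:, 0] @ model.U[:, 0]) > 1 - 1e-6
            assert abs(Vt[0] @ model.V[:, 0]) > 1 - 1e-6

    def test_planted_support_recovered_at_binding_penalty(self):
        X, Y, link = make_linked_edge_datasets(17, 60, 60, 4, 2.0, 0.2, seed=4)
        model = scca_fit(X, Y, 2.0, 2.0, K=1)
        u = model.U[:, 0]
        assert np.all(u[link.u_support] != 0)
        off = np.delete(np.arange(60), link.u_support)
        # binding L1 bound concentrates the mass on the planted support
        assert np.abs(u[off]).sum() < 0.15 * np.abs(u).sum()
        assert np.count_nonzero(u[off]) < 30

    def test_objective_monotone_and_constraints(self, rng):
        for _ in range(5):
            X = rng.standard_normal((12, 30))
            Y = rng.standard_normal((12, 25))
            c1, c2 = 0.4 * np.sqrt(30), 0.4 * np.sqrt(25)
            model = scca_fit(X, Y, c1, c2, K=3)
            for hist in model.objective_history:
                assert np.all(np.diff(hist) >= -1e-9)
            for k in range(model.K):
                assert np.linalg.norm(model.U[:, k]) <= 1 + 1e-8
                assert np.abs(model.U[:, k]).sum() <= c1 + 1e-6
                assert np.linalg.norm(model.V[:, k]) <= 1 + 1e-8
                assert np.abs(model.V[:, k]).sum() <= c2 + 1e-6

    def test_canonical_correlations_in_range(self, rng):
        X = rng.standard_normal((15, 20))
        Y = rng.standard_normal((15, 20))
        model = scca_fit(X, Y, 2.0, 2.0, K=4)
        assert np.all(np.abs(model.D) <= 1 + 1e-12)

    def test_swap_symmetry_on_unique_optimum(self):
        X, Y, _ = make_linked_edge_datasets(12, 20, 15, 3, 2.0, 0.0, seed=8)
        a = scca_fit(X, Y, 2.0, 1.8, K=1)
        b = scca_fit(Y, X, 1.8, 2.0, K=1)
        assert abs(a.U[:, 0] @ b.V[:, 0]) == pytest.approx(1.0, abs=1e-6)
        assert abs(a.V[:, 0] @ b.U[:, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_k_capped_at_rank_with_warning(self, rng):
        X = rng.standard_normal((5, 10))
        Y = rng.standard_normal((5, 10))
        with pytest.warns(UserWarning, match="exceeds min rank"):
            model = scca_fit(X, Y, 2.0, 2.0, K=8)
        assert model.K <= 4

    def test_penalty_range_validated(self, rng):
        X = rng.standard_normal((8, 9))
        with pytest.raises(ValueError, match="c1"):
            scca_fit(X, X, 0.5, 2.0)
        with pytest.raises(ValueError, match="c2"):
            scca_fit(X, X, 2.0, 4.0)

    def test_subject_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="same number of subjects"):
            scca_fit(rng.standard_normal((8, 4)), rng.standard_normal((7, 4)), 1.5, 1.5)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.standard_normal((10, 8))
        Y = rng.standard_normal((10, 6))
        model = scca_fit(X, Y, 2.0, 2.0, K=2)
        path = tmp_path / "model.npz"
        model.save(path)
        from conncca.scca import SccaModel

        back = SccaModel.load(path)
        np.testing.assert_array_equal(back.U, model.U)
        np.testing.assert_array_equal(back.D, model.D)
        assert back.c1 == model.c1


class TestSelectPenalties:
    def test_single_point_grid_returned(self, rng):
        X = rng.standard_normal((12, 10))
        Y = rng.standard_normal((12, 10))
        c1, c2, table = select_penalties(X, Y, [(2.0, 2.5)], n_perm=10, seed=0)
        assert (c1, c2) == (2.0, 2.5)
        assert len(table) == 1

    def test_strong_linkage_scores_significant(self):
        X, Y, _ = make_linked_edge_datasets(17, 50, 50, 4, 2.0, 0.2, seed=1)
        grid = default_penalty_grid(50, 50, n_points=3)
        _, _, table = select_penalties(X, Y, grid, n_perm=25, seed=1)
        assert table.score.max() > 2

    def test_pure_noise_rarely_scores_significant(self, rng):
        hits = 0
        n_reps = 12
        grid = [
            (max(1.0, f * np.sqrt(40)), max(1.0, f * np.sqrt(40)))
            for f in (0.15, 0.3, 0.6)
        ]
        for r in range(n_reps):
            X = rng.standard_normal((17, 40))
            Y = rng.standard_normal((17, 40))
            _, _, table = select_penalties(X, Y, grid, n_perm=30, seed=r)
            hits += table.score.max() > 2
        assert hits <= 0.1 * n_reps + 1

    def test_minimum_permutations_enforced(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="10 permutations"):
            select_penalties(X, X, [(1.5, 1.5)], n_perm=5)
        with pytest.raises(ValueError, match="grid is empty"):
            select_penalties(X, X, [], n_perm=10)


class TestPrediction:
    def _connectome_fixture(self, rng, n=10, R=8):
        # edge datasets derived from valid SPD connectomes with a shared
        # rank-one subject factor, so exact recovery implies SPD output
        labels = [f"r{i}" for i in range(R)]
        iu_len = R * (R - 1) // 2
        base = 0.05 * rng.standard_normal(iu_len)
        direction = rng.standard_normal(iu_len)
        direction /= np.linalg.norm(direction)
        t = rng.normal(0, 0.03, size=n)
        rows = base + np.outer(t, direction)
        return (
            EdgeDataset(rows, edge_index_for(labels)),
            EdgeDataset(np.roll(rows, 1, axis=1), edge_index_for(labels)),
            labels,
        )

    def test_mean_input_maps_to_mean_output(self, rng):
        X = rng.standard_normal((10, 12))
        Y = rng.standard_normal((10, 9))
        model = scca_fit(X, Y, 2.0, 2.0, K=2)
        np.testing.assert_allclose(
            predict_y_from_x(model, model.x_means), model.y_means, atol=1e-12
        )
        np.testing.assert_allclose(
            predict_x_from_y(model, model.y_means), model.x_means, atol=1e-12
        )

    def test_noiseless_rank_one_exact_recovery_both_directions(self):
        X, Y, _ = make_linked_edge_datasets(10, 30, 25, 4, 1.5, 0.0, seed=3)
        model = scca_fit(
            X.matrix[:9], Y.matrix[:9], np.sqrt(30), np.sqrt(25), K=1
        )
        y_hat = predict_y_from_x(model, X.matrix[9])
        x_hat = predict_x_from_y(model, Y.matrix[9])
        assert np.linalg.norm(y_hat - Y.matrix[9]) < 1e-6 * np.linalg.norm(Y.matrix[9])
        assert np.linalg.norm(x_hat - X.matrix[9]) < 1e-6 * np.linalg.norm(X.matrix[9])

    def test_predicted_connectome_is_spd_on_connectome_fixture(self, rng):
        X, Y, labels = self._connectome_fixture(rng)
        model = scca_fit(X.matrix[:9], Y.matrix[:9], 2.0, 2.0, K=1)
        y_hat = predict_y_from_x(model, X.matrix[9])
        assert check_spd(devectorize(y_hat, labels))[0]

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((10, 12))
        Y = rng.standard_normal((10, 9))
        model = scca_fit(X, Y, 2.0, 2.0, K=1)
        with pytest.raises(ValueError, match="features"):
            predict_y_from_x(model, np.zeros(9))
        with pytest.raises(ValueError, match="features"):
            predict_x_from_y(model, np.zeros(12))
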