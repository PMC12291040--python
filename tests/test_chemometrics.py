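"""Autoscaling, Kennard-Stone partitioning and PCA diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npscreen as nps
from npscreen.chemometrics import critical_limits, pca_fit, project


def brute_force_kennard_stone(X, train_size):
    """Independent maximin oracle: plain loops, full recomputation each step."""
    n = len(X)
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sqrt(np.sum((X[i] - X[j]) ** 2)))
            if d > best:
                best, pair = d, (i, j)
    selected = list(pair)
    while len(selected) < train_size:
        best_idx, best_min = None, -1.0
        for c in range(n):
            if c in selected:
                continue
            dmin = min(
                float(np.sqrt(np.sum((X[c] - X[s]) ** 2))) for s in selected
            )
            if dmin > best_min:  # strict: ties keep the lowest candidate index
                best_min, best_idx = dmin, c
        selected.append(best_idx)
    return selected


class TestAutoscale:
    def test_symmetric_three_point_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        _, scaled = nps.autoscale_fit(X)
        np.testing.assert_allclose(scaled[:, 0], [-1, 0, 1])

    def test_scaled_columns_have_zero_mean_unit_sd(self, gaussian_class):
        _, scaled = nps.autoscale_fit(gaussian_class)
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_mean_imputed_cell_scales_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, np.nan], [3.0, 7.0]])
        _, scaled = nps.autoscale_fit(X, missing_policy="mean_impute")
        assert scaled[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_fill_policy(self):
        X = np.array([[1.0, 5.0], [2.0, np.nan], [3.0, 7.0]])
        params, _ = nps.autoscale_fit(X, missing_policy="zero_fill")
        assert params.column_means[1] == pytest.approx(4.0)  # mean of (5, 0, 7)

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="x1"):
            nps.autoscale_fit(X)

    def test_scaling_then_unscaling_is_identity(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        np.testing.assert_allclose(
            nps.invert_scaling(params, scaled), gaussian_class, atol=1e-9
        )

    def test_base_peak_reference_yields_unscalable_first_loss_column(self):
        # in base-peak mode the top fragment's loss is identically zero
        panel = nps.generate_panel(nps.well_separated_templates()[:2], 5, seed=1)
        matrix = nps.build_matrix(panel.records, nl_reference="base_peak")
        with pytest.raises(ValueError, match="nl1"):
            nps.autoscale_fit(matrix)


class TestKennardStone:
    def test_collinear_points_pick_the_extremes(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        result = nps.kennard_stone_split(X, train_fraction=0.5)
        assert result.train_indices == [0, 3]
        assert result.test_indices == [1, 2]

    def test_fraction_one_selects_everything_as_a_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 3))
        result = nps.kennard_stone_split(X, train_fraction=1.0)
        assert result.train_indices == list(range(7))
        assert sorted(result.selection_order) == list(range(7))
        assert result.test_indices == []

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            p = int(rng.integers(1, 9))
            X = rng.normal(size=(n, p))
            k = int(rng.integers(2, n + 1))
            result = nps.kennard_stone_split(X, train_size=k)
            assert result.selection_order == brute_force_kennard_stone(X, k)

    def test_duplicate_rows_tie_break_to_lowest_index(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        result = nps.kennard_stone_split(X, train_size=3)
        # seed pair (0, 2); third pick ties at distance 0 -> lowest index 1
        assert result.selection_order == [0, 2, 1]

    def test_absolute_train_size_overrides_fraction(self):
        X = np.arange(10.0)[:, None]
        result = nps.kennard_stone_split(X, train_size=4)
        assert len(result.train_indices) == 4
        assert len(result.test_indices) == 6


class TestPca:
    def test_full_rank_reconstruction_is_exact(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 8, params)
        scores, _, q = project(model, gaussian_class)
        recon = scores @ model.loadings.T
        assert np.max(np.abs(recon - scaled)) < 1e-8
        assert np.max(q) < 1e-8

    def test_eigenvalues_sum_to_total_variance(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 8, params)
        assert model.eigenvalues.sum() == pytest.approx(8.0, abs=1e-6)

    def test_loadings_orthonormal_and_eigenvalues_descending(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 4, params)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_scores_are_uncorrelated(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 4, params)
        scores, _, _ = project(model, gaussian_class)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_sign_convention_matches_sklearn_up_to_sign(self, gaussian_class):
        sklearn = pytest.importorskip("sklearn.decomposition")
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        sk = sklearn.PCA(n_components=3).fit(scaled)
        for a in range(3):
            ours, theirs = model.loadings[:, a], sk.components_[a]
            agreement = min(
                np.max(np.abs(ours - theirs)), np.max(np.abs(ours + theirs))
            )
            assert agreement < 1e-8
            assert model.eigenvalues[a] == pytest.approx(
                sk.explained_variance_[a], rel=1e-10
            )

    def test_two_cluster_data_separated_along_pc1(self):
        rng = np.random.default_rng(9)
        X = np.vstack(
            [rng.normal(0, 1, size=(100, 8)), rng.normal(6, 1, size=(100, 8))]
        )
        labels = np.array([0] * 100 + [1] * 100)
        params, scaled = nps.autoscale_fit(X)
        model = pca_fit(scaled, 2, params)
        scores, _, _ = project(model, X)
        side = scores[:, 0] > 0
        agreement = max(np.mean(side == labels), np.mean(side != labels))
        assert agreement >= 0.95

    def test_component_count_out_of_range_rejected(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        with pytest.raises(ValueError):
            pca_fit(scaled, 0, params)
        with pytest.raises(ValueError):
            pca_fit(scaled, 9, params)


class TestProjectionDiagnostics:
    def test_training_mean_has_zero_scores_and_t2(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        scores, t2, _ = project(model, gaussian_class.mean(axis=0))
        np.testing.assert_allclose(scores, 0, atol=1e-10)
        assert t2[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("A", [1, 3, 5])
    def test_mean_training_t2_identity(self, gaussian_class, A):
        # algebraic identity: mean T2 over the training set = A (n-1)/n
        n = len(gaussian_class)
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, A, params)
        _, t2, _ = project(model, gaussian_class)
        assert t2.mean() == pytest.approx(A * (n - 1) / n, abs=1e-6)

    def test_projection_invariant_to_row_order(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        _, t2, q = project(model, gaussian_class)
        perm = np.random.default_rng(1).permutation(len(gaussian_class))
        _, t2p, qp = project(model, gaussian_class[perm])
        np.testing.assert_allclose(t2p, t2[perm], rtol=1e-12)
        np.testing.assert_allclose(qp, q[perm], rtol=1e-12)

    def test_projection_reproduces_fit_scores(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        fit_scores = scaled @ model.loadings
        proj_scores, _, _ = project(model, gaussian_class)
        np.testing.assert_allclose(proj_scores, fit_scores, atol=1e-10)


class TestCriticalLimits:
    def test_training_exceedance_near_alpha(self):
        # large-n Gaussian calibration of both limits at the 95% level
        rng = np.random.default_rng(42)
        X = rng.normal(size=(2000, 8)) @ np.diag([3, 2.5, 2, 1.5, 1, 0.8, 0.5, 0.3])
        params, scaled = nps.autoscale_fit(X)
        model = pca_fit(scaled, 4, params)
        _, t2, q = project(model, X)
        se2 = 2 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs((t2 > model.t2_limit).mean() - 0.05) < se2
        assert abs((q > model.q_limit).mean() - 0.05) < se2

    def test_limits_tighten_with_larger_alpha(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        t2_strict, q_strict = critical_limits(model, alpha=0.5)
        t2_loose, q_loose = critical_limits(model, alpha=0.05)
        assert t2_strict < t2_loose
        assert q_strict < q_loose

    def test_jackson_mudholkar_alternative_is_close_to_moment_limit(
        self, gaussian_class
    ):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 4, params)
        _, q_m = critical_limits(model, 0.05, "moment_chi2")
        _, q_jm = critical_limits(model, 0.05, "jackson_mudholkar")
        assert q_jm == pytest.approx(q_m, rel=0.25)

    def test_n_equal_a_edge_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 8))
        params, scaled = nps.autoscale_fit(X)
        model = pca_fit(scaled, 4, params)  # A = n - 1 is legal
        model.n_train = 4
        with pytest.raises(ValueError):
            critical_limits(model, 0.05)


class TestInfluenceTable:
    def test_flags_match_independent_recomputation(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        table = nps.influence_table(model, gaussian_class)
        expected = (table["t2"] > model.t2_limit) | (table["q"] > model.q_limit)
        assert (table["outlier"] == expected).all()

    def test_far_outlier_is_flagged(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        outlier = gaussian_class.mean(axis=0).copy()
        outlier[5] += 20 * gaussian_class[:, 5].std()
        table = nps.influence_table(model, outlier[None, :])
        assert bool(table["outlier"].iloc[0])

    def test_central_sample_is_not_flagged(self, gaussian_class):
        params, scaled = nps.autoscale_fit(gaussian_class)
        model = pca_fit(scaled, 3, params)
        table = nps.influence_table(model, gaussian_class.mean(axis=0)[None, :])
        assert not bool(table["outlier"].iloc[0])
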