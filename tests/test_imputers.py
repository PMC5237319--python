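"""Imputation algorithms: contracts, exact limits and oracle equivalence."""

import numpy as np
import pytest

from imputebench import (
    ExpressionMatrix,
    ImputerSpec,
    SyntheticSpec,
    available_algorithms,
    generate_complete,
    impute,
    make_imputer,
    make_mask,
)
from imputebench.imputers import REGISTRY, default_lls_k
from imputebench.imputers.base import ImputationError

from conftest import make_masked
from oracles import knn_oracle, lls_oracle, ls_oracle

ALL_IDS = available_algorithms()


def _matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    return ExpressionMatrix([f"g{i}" for i in range(n)], [f"s{j}" for j in range(s)], values, groups)


class TestRegistry:
    def test_roster_is_twelve_algorithms_plus_two_baselines(self):
        assert len(ALL_IDS) == 14
        assert set(ALL_IDS) >= {"zero", "row_average", "svd", "bpca", "knn", "sknn",
                                "iknn", "ls", "lls", "slls", "ills", "shrink_lls",
                                "shrink_slls", "shrink_ills"}

    def test_unknown_algorithm_and_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_imputer("magic")
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            make_imputer("knn", bandwidth=3)

    def test_sklearn_params_round_trip(self):
        est = make_imputer("knn", k=7)
        assert est.get_params() == {"k": 7}
        est.set_params(k=3)
        assert est.get_params()["k"] == 3

    def test_default_lls_neighbourhood(self):
        assert default_lls_k(300) == 30
        assert default_lls_k(10) == 5
        assert default_lls_k(10_000) == 150


class TestUniversalContracts:
    @pytest.mark.parametrize("algorithm_id", ALL_IDS)
    def test_zero_missing_input_is_identity(self, algorithm_id, small_matrix):
        est = make_imputer(algorithm_id)
        out = est.fit_transform(small_matrix.values)
        np.testing.assert_array_equal(out, small_matrix.values)

    @pytest.mark.parametrize("algorithm_id", ALL_IDS)
    def test_observed_cells_preserved_bit_exactly(self, algorithm_id, default_synthetic):
        m, _ = default_synthetic
        masked = make_mask(m, 0.05, seed=13)
        res = impute(ImputerSpec(algorithm_id), masked)
        obs = ~masked.mask
        assert np.array_equal(res.imputed[obs], m.values[obs])
        assert not np.isnan(res.imputed).any()

    @pytest.mark.parametrize("algorithm_id", ALL_IDS)
    def test_determinism_under_fixed_seed(self, algorithm_id, small_matrix):
        masked = make_masked(small_matrix, [(0, 1), (3, 2), (5, 0)])
        a = impute(ImputerSpec(algorithm_id, seed=3), masked)
        b = impute(ImputerSpec(algorithm_id, seed=3), masked)
        np.testing.assert_array_equal(a.imputed, b.imputed)

    def test_all_missing_row_rejected(self):
        v = np.ones((3, 4))
        v[1] = np.nan
        with pytest.raises(ImputationError):
            make_imputer("knn").fit_transform(v)


class TestBaselines:
    def test_zero_fills_masked_cells_with_zero(self, small_matrix):
        masked = make_masked(small_matrix, [(1, 1), (4, 3)])
        res = impute(ImputerSpec("zero"), masked)
        assert res.imputed[1, 1] == 0.0 and res.imputed[4, 3] == 0.0

    def test_row_average_mean_arithmetic(self):
        m = _matrix([[1.0, 3.0, 5.0], [2.0, 2.0, 2.0], [0.0, 4.0, 8.0]])
        masked = make_masked(m, [(0, 2)])
        res = impute(ImputerSpec("row_average"), masked)
        assert res.imputed[0, 2] == pytest.approx(2.0)  # mean of observed {1, 3}


class TestKNNFamily:
    def test_k1_single_missing_cell_takes_nearest_neighbour_value(self, small_matrix):
        masked = make_masked(small_matrix, [(0, 2)])
        res = impute(ImputerSpec("knn", {"k": 1}), masked)
        np.testing.assert_allclose(res.imputed, knn_oracle(masked.values, k=1))
        # g1 is by far the closest gene to g0; its value at s2 dominates
        assert res.imputed[0, 2] == pytest.approx(small_matrix.values[1, 2], abs=1e-9)

    def test_equidistant_tie_broken_by_lower_row_index(self):
        m = _matrix([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0], [0.0, 0.0, 9.0], [9.0, 9.0, 3.0]])
        # g1 and g2 are equidistant from g0 on (s0, s1); tie goes to g1
        masked = make_masked(m, [(0, 2)])
        res = impute(ImputerSpec("knn", {"k": 1}), masked)
        assert res.imputed[0, 2] == pytest.approx(7.0, abs=1e-9)
        np.testing.assert_allclose(res.imputed, knn_oracle(masked.values, k=1))

    def test_duplicated_row_recovered_exactly_with_k1(self, small_matrix):
        dup = np.vstack([small_matrix.values, small_matrix.values])
        m = _matrix(dup)
        masked = make_masked(m, [(2, 3)])
        res = impute(ImputerSpec("knn", {"k": 1}), masked)
        assert res.imputed[2, 3] == pytest.approx(small_matrix.values[2, 3], abs=1e-9)

    def test_sknn_processes_ascending_missing_count(self, small_matrix):
        masked = make_masked(small_matrix, [(0, 0), (0, 1), (2, 3)])
        res = impute(ImputerSpec("sknn", {"k": 2}), masked)
        assert not np.isnan(res.imputed).any()

    def test_iknn_converges_and_reports_iterations(self, default_synthetic):
        m, _ = default_synthetic
        masked = make_mask(m, 0.05, seed=5)
        res = impute(ImputerSpec("iknn", {"k": 10}), masked)
        assert res.diagnostics["iterations"] >= 1

    def test_fallback_to_row_average_counted(self):
        # every other gene is missing at g0's missing column -> no candidate
        v = np.array([[1.0, 2.0, np.nan], [1.1, 2.1, np.nan], [0.9, 1.9, np.nan]])
        est = make_imputer("knn", k=2)
        out = est.transform(v)
        assert est.diagnostics_["fallback_cells"] == 3
        np.testing.assert_allclose(out[:, 2], np.nanmean(v, axis=1))


class TestSVD:
    def test_rank1_matrix_recovered(self):
        u = np.arange(1, 9, dtype=float)
        v = np.array([2.0, -1.0, 0.5, 3.0])
        m = _matrix(np.outer(u, v))
        masked = make_masked(m, [(0, 1), (4, 2)])
        res = impute(ImputerSpec("svd", {"rank": 1, "tol": 1e-10}), masked)
        np.testing.assert_allclose(res.imputed, m.values, atol=1e-6)

    def test_zero_matrix_imputes_zero(self):
        m = _matrix(np.zeros((5, 4)))
        masked = make_masked(m, [(1, 2)])
        res = impute(ImputerSpec("svd", {"rank": 1}), masked)
        assert res.imputed[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_rank2_synthetic_recovered(self):
        m, _ = generate_complete(SyntheticSpec(n_genes=80, n_clusters=2, de_fraction=0.0,
                                               noise_sd=0.0, seed=11))
        masked = make_mask(m, 0.05, seed=1)
        res = impute(ImputerSpec("svd", {"rank": 2, "tol": 1e-12, "max_iter": 500}), masked)
        assert np.max(np.abs(res.imputed - m.values)) < 1e-4

    def test_rank_out_of_bounds_rejected(self, small_matrix):
        masked = make_masked(small_matrix, [(0, 0)])
        with pytest.raises(ValueError, match="rank"):
            impute(ImputerSpec("svd", {"rank": 9}), masked)


class TestBPCA:
    def test_beats_row_average_on_low_rank_data(self):
        # rank-2 column structure + tiny noise: the latent-factor model should
        # exploit the sample correlations a per-gene mean cannot see
        rng = np.random.default_rng(21)
        values = rng.normal(size=(120, 2)) @ rng.normal(size=(2, 6)) + rng.normal(scale=0.05, size=(120, 6))
        m = _matrix(values)
        masked = make_mask(m, 0.05, seed=2)
        cells = masked.mask
        bp = impute(ImputerSpec("bpca"), masked)
        ra = impute(ImputerSpec("row_average"), masked)
        mse = lambda r: np.mean((r.imputed[cells] - m.values[cells]) ** 2)
        assert mse(bp) < mse(ra)

    def test_seed_determinism(self, default_synthetic):
        m, _ = default_synthetic
        masked = make_mask(m, 0.05, seed=3)
        a = impute(ImputerSpec("bpca", seed=5), masked)
        b = impute(ImputerSpec("bpca", seed=5), masked)
        np.testing.assert_array_equal(a.imputed, b.imputed)


class TestLS:
    def test_exact_affine_relation_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = _matrix(np.vstack([2 * x + 1, x, x[::-1] + 0.3]))
        masked = make_masked(m, [(0, 4)])
        res = impute(ImputerSpec("ls", {"k": 1}), masked)
        assert res.imputed[0, 4] == pytest.approx(2 * 5.0 + 1, abs=1e-9)

    def test_constant_neighbours_take_fallback_path(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [7.0, 7.0, 7.0, 7.0]])
        masked = make_masked(m, [(0, 3)])
        est = make_imputer("ls", k=2)
        out = est.transform(masked.values)
        assert est.diagnostics_["fallback_cells"] == 1
        assert out[0, 3] == pytest.approx(2.0)  # row average of {1, 2, 3}

    def test_matches_oracle_on_worked_case(self, small_matrix):
        masked = make_masked(small_matrix, [(1, 0), (3, 3)])
        res = impute(ImputerSpec("ls", {"k": 2}), masked)
        np.testing.assert_allclose(res.imputed, ls_oracle(masked.values, k=2), atol=1e-9)


class TestLLSFamily:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(8)
        n1, n2 = rng.normal(size=6), rng.normal(size=6)
        target = 1.5 * n1 - 0.7 * n2
        far = rng.normal(size=6) + 10  # kept far away so n1, n2 are the neighbours
        m = _matrix(np.vstack([target, n1, n2, far]))
        masked = make_masked(m, [(0, 5)])
        res = impute(ImputerSpec("lls", {"k": 2}), masked)
        assert res.imputed[0, 5] == pytest.approx(target[5], abs=1e-8)

    def test_k1_duplicated_rows(self, small_matrix):
        dup = np.vstack([small_matrix.values, small_matrix.values])
        masked = make_masked(_matrix(dup), [(4, 1)])
        res = impute(ImputerSpec("lls", {"k": 1}), masked)
        assert res.imputed[4, 1] == pytest.approx(small_matrix.values[4, 1], abs=1e-9)

    def test_matches_bruteforce_oracle(self, small_matrix):
        masked = make_masked(small_matrix, [(0, 1), (2, 2), (5, 3)])
        res = impute(ImputerSpec("lls", {"k": 3}), masked)
        np.testing.assert_allclose(res.imputed, lls_oracle(masked.values, k=3), atol=1e-8)

    def test_shrinkage_variants_complete_and_preserve(self, default_synthetic):
        m, _ = default_synthetic
        masked = make_mask(m, 0.08, seed=9)
        for aid in ("shrink_lls", "shrink_slls", "shrink_ills"):
            res = impute(ImputerSpec(aid), masked)
            assert not np.isnan(res.imputed).any()

    def test_shrinkage_never_inflates_coefficients(self):
        from imputebench.imputers.lls import _js_shrinkage

        rng = np.random.default_rng(2)
        for _ in range(50):
            w = rng.normal(size=6)
            resid = rng.normal(size=4)
            c = _js_shrinkage(w, resid, n_obs=10)
            assert 0.0 <= c <= 1.0
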