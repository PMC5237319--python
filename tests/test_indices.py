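"""Performance indices: hand-worked values, invariances and error modes."""

import numpy as np
import pytest

from imputebench import ExpressionMatrix, blci, cpp, inv_nrmse
from imputebench.indices import INV_NRMSE_CAP, IndexError_, default_groups

from conftest import make_masked
from oracles import blci_oracle, cpp_pairs_oracle, inv_nrmse_oracle


def _matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    return ExpressionMatrix([f"g{i}" for i in range(n)], [f"s{j}" for j in range(s)], values, groups)


class TestInvNRMSE:
    def test_perfect_imputation_hits_cap(self, small_matrix):
        masked = make_masked(small_matrix, [(0, 0), (2, 2), (4, 1)])
        score = inv_nrmse(small_matrix, small_matrix.values, masked)
        assert score.value == INV_NRMSE_CAP

    def test_hand_arithmetic_two_cells(self):
        # true masked values {0, 2} (population SD 1), imputed {1, 1}:
        # RMSE = 1, NRMSE = 1, score = 1
        m = _matrix([[0.0, 5.0, 5.0], [2.0, 6.0, 6.0]])
        mask = np.zeros((2, 3), dtype=bool)
        mask[0, 0] = mask[1, 0] = True
        imputed = m.values.copy()
        imputed[0, 0] = 1.0
        imputed[1, 0] = 1.0
        score = inv_nrmse(m, imputed, mask)
        assert score.value == pytest.approx(1.0)
        assert score.components["nrmse"] == pytest.approx(1.0)

    def test_affine_invariance(self, small_matrix, rng):
        masked = make_masked(small_matrix, [(1, 1), (3, 0), (5, 2)])
        imputed = small_matrix.values + rng.normal(size=small_matrix.shape) * masked.mask
        v1 = inv_nrmse(small_matrix, imputed, masked).value
        shifted = _matrix(3.0 + 2.5 * small_matrix.values)
        v2 = inv_nrmse(shifted, 3.0 + 2.5 * imputed, masked).value
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_degenerate_mask_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0], [1.0, 4.0, 5.0]])
        mask = np.zeros((2, 3), dtype=bool)
        mask[0, 0] = mask[1, 0] = True  # identical true values, SD 0
        with pytest.raises(IndexError_, match="degenerate"):
            inv_nrmse(m, np.zeros((2, 3)), mask)

    def test_matches_naive_formula_on_random_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            true_vals = rng.normal(size=n)
            imp_vals = true_vals + rng.normal(scale=0.5, size=n)
            m = _matrix(np.column_stack([true_vals, rng.normal(size=n), rng.normal(size=n)]))
            mask = np.zeros((n, 3), dtype=bool)
            mask[:, 0] = True
            imputed = m.values.copy()
            imputed[:, 0] = imp_vals
            got = inv_nrmse(m, imputed, mask).value
            assert got == pytest.approx(inv_nrmse_oracle(true_vals, imp_vals), rel=1e-9)


class TestCPP:
    def test_identical_matrices_score_one(self, default_synthetic):
        m, _ = default_synthetic
        assert cpp(m, m.values, k_clusters=3, seed=1).value == 1.0

    def test_worked_pair_example(self):
        """Complete clustering {ABC}{DEF} vs imputed {AB}{CDEF}: 4 of 6
        co-clustered pairs survive."""
        complete_labels = np.array([0, 0, 0, 1, 1, 1])
        imputed_labels = np.array([0, 0, 1, 1, 1, 1])
        from imputebench.indices import _copair_counts

        preserved, total = _copair_counts(complete_labels, imputed_labels)
        assert (preserved, total) == (4, 6)
        assert preserved / total == pytest.approx(
            cpp_pairs_oracle(complete_labels, imputed_labels)
        )

    def test_pair_counting_matches_oracle_on_random_labelings(self, rng):
        from imputebench.indices import _copair_counts

        for _ in range(300):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            if len(set(a)) == n:  # all singletons: undefined, skipped
                continue
            preserved, total = _copair_counts(a, b)
            assert preserved / total == pytest.approx(cpp_pairs_oracle(a, b))

    def test_invariant_under_cluster_relabeling(self, rng):
        from imputebench.indices import _copair_counts

        a = rng.integers(0, 3, size=25)
        b = rng.integers(0, 3, size=25)
        perm = np.array([2, 0, 1])
        assert _copair_counts(a, b) == _copair_counts(perm[a], perm[b])

    def test_disjoint_clusterings_score_zero(self):
        m, _ = None, None
        complete_labels = np.array([0, 0, 1, 1])
        imputed_labels = np.array([0, 1, 0, 1])
        from imputebench.indices import _copair_counts

        preserved, total = _copair_counts(complete_labels, imputed_labels)
        assert preserved == 0 and total == 2

    def test_fewer_genes_than_clusters_rejected(self):
        m = _matrix(np.eye(3))
        with pytest.raises(IndexError_):
            cpp(m, m.values, k_clusters=10)


class TestBLCI:
    def _de_setup(self, rng, n=40, n_de=8, shift=4.0):
        values = rng.normal(size=(n, 6)) + 6.0
        values[:n_de, 3:] += shift
        return _matrix(values, groups=["A"] * 3 + ["B"] * 3)

    def test_identical_matrices_score_one(self, rng):
        m = self._de_setup(rng)
        assert blci(m, m.values).value == 1.0

    def test_worked_set_arithmetic(self):
        """|D_o|=4, |D_o & D_i|=3, |D_o^c & D_i^c|=5 of 6 -> 3/4 + 5/6 - 1."""
        d_o = {0, 1, 2, 3}
        d_i = {1, 2, 3, 4}
        total = set(range(10))
        assert blci_oracle(d_o, d_i, total) == pytest.approx(3 / 4 + 5 / 6 - 1)

    def test_matches_oracle_on_random_call_sets(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 50))
            d_o = set(int(i) for i in rng.choice(n, size=int(rng.integers(1, n - 1)), replace=False))
            d_i = set(int(i) for i in rng.choice(n, size=int(rng.integers(0, n)), replace=False))
            all_genes = set(range(n))
            tp = len(d_o & d_i)
            tn = len((all_genes - d_o) & (all_genes - d_i))
            direct = tp / len(d_o) + tn / (n - len(d_o)) - 1.0
            assert direct == pytest.approx(blci_oracle(d_o, d_i, all_genes))

    def test_group_label_swap_invariance(self, rng):
        m = self._de_setup(rng)
        imputed = m.values + rng.normal(scale=0.3, size=m.shape)
        v1 = blci(m, imputed, groups=["A"] * 3 + ["B"] * 3).value
        v2 = blci(m, imputed, groups=["B"] * 3 + ["A"] * 3).value
        assert v1 == pytest.approx(v2)

    def test_default_groups_are_half_split(self):
        assert default_groups(6) == ["A", "A", "A", "B", "B", "B"]
        assert default_groups(9) == ["A"] * 4 + ["B"] * 5

    def test_degenerate_de_sets_rejected(self, rng):
        flat = _matrix(rng.normal(size=(20, 6)), groups=["A"] * 3 + ["B"] * 3)
        with pytest.raises(IndexError_, match="degenerate|alpha"):
            blci(flat, flat.values, alpha=1e-12)  # no gene ever significant

    def test_single_group_rejected(self, rng):
        m = _matrix(rng.normal(size=(10, 4)))
        with pytest.raises(IndexError_, match="2 groups"):
            blci(m, m.values, groups=["A", "A", "A", "A"])


class TestMonotoneDegradation:
    def test_noise_does_not_improve_median_inv_nrmse(self, small_matrix, rng):
        masked = make_masked(small_matrix, [(0, 0), (1, 2), (3, 1), (5, 3)])
        sds = [0.1, 0.5, 1.5]
        medians = []
        for sd in sds:
            vals = []
            for _ in range(50):
                imputed = small_matrix.values.copy()
                imputed[masked.mask] += rng.normal(scale=sd, size=4)
                vals.append(inv_nrmse(small_matrix, imputed, masked).value)
            medians.append(np.median(vals))
        assert medians[0] >= medians[1] >= medians[2]
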