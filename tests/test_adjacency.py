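"""Supervised similarity matrices, masks and neighbour selection."""

import numpy as np
import pandas as pd
import pytest

from npembed import (DataError, SubjectTable, age_similarity, apply_constraints,
                     combine_and_select, image_similarity)


def _table(ages, sexes, sites):
    n = len(ages)
    return SubjectTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": ages, "sex": sexes, "site": sites}), ("F", "M"))


class TestImageSimilarity:
    def test_identical_rows_have_similarity_one(self, rng):
        X = rng.normal(size=(4, 3))
        X[1] = X[0]
        A = image_similarity(X, bandwidth=1.0)
        assert A.values[0, 1] == pytest.approx(1.0)

    def test_median_pair_maps_to_exp_minus_one(self):
        # collinear points 0, 1, 3: nonzero squared distances 1, 4, 9
        X = np.array([[0.0], [1.0], [3.0]])
        A = image_similarity(X, bandwidth="auto")
        assert A.values[1, 2] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        sigma = 1.7
        A = image_similarity(X, bandwidth=sigma)
        for i in range(5):
            for j in range(5):
                expected = np.exp(-np.sum((X[i] - X[j]) ** 2) / sigma ** 2)
                assert A.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_identical_rows_auto_bandwidth_error(self):
        with pytest.raises(DataError, match="identical"):
            image_similarity(np.ones((4, 2)), bandwidth="auto")


class TestAgeSimilarity:
    def test_equal_ages_similarity_one(self):
        a = age_similarity(np.array([7.0, 7.0, 9.0]), bandwidth=2.0)
        assert a.values[0, 1] == pytest.approx(1.0)

    def test_scaled_identity(self):
        a = age_similarity(np.array([3.0, 21.0]), bandwidth=18.0)
        assert a.values[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-14)

    def test_matches_double_loop_oracle(self, rng):
        ages = rng.uniform(3, 21, size=6)
        tau = 4.2
        a = age_similarity(ages, bandwidth=tau)
        for i in range(6):
            for j in range(6):
                expected = np.exp(-((ages[i] - ages[j]) / tau) ** 2)
                assert a.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_equal_ages_auto_bandwidth_error(self):
        with pytest.raises(DataError, match="identical"):
            age_similarity(np.full(5, 10.0), bandwidth="auto")


class TestConstraints:
    def test_sex_mismatch_zeroed(self, rng):
        table = _table([5, 6, 7], ["M", "F", "M"], ["A", "B", "C"])
        A = image_similarity(rng.normal(size=(3, 2)), bandwidth=1.0)
        M = apply_constraints(A, table)
        assert M[0, 1] == 0.0 and M[1, 0] == 0.0
        assert M[0, 2] > 0.0

    def test_same_site_zeroed_when_enabled(self, rng):
        table = _table([5, 6, 7], ["M", "M", "M"], ["A", "A", "B"])
        A = image_similarity(rng.normal(size=(3, 2)), bandwidth=1.0)
        M = apply_constraints(A, table, use_site=True)
        assert M[0, 1] == 0.0
        assert M[0, 2] > 0.0

    def test_single_site_cohort_fully_masked(self, rng):
        table = _table([5, 6, 7, 8], ["M"] * 4, ["A"] * 4)
        A = image_similarity(rng.normal(size=(4, 2)), bandwidth=1.0)
        M = apply_constraints(A, table, use_site=True)
        assert np.all(M == 0.0)


class TestCombineAndSelect:
    def test_top_k_selection_order(self):
        C_img = np.array([[0.0, 0.9, 0.8, 0.7],
                          [0.9, 0.0, 0.5, 0.4],
                          [0.8, 0.5, 0.0, 0.3],
                          [0.7, 0.4, 0.3, 0.0]])
        ones = np.ones((4, 4))
        g = combine_and_select(C_img, ones, k=2, mode="product")
        np.testing.assert_array_equal(g.neighbours[0], [1, 2])

    def test_exact_tie_prefers_smaller_index(self):
        C = np.array([[0.0, 0.6, 0.6], [0.6, 0.0, 0.2], [0.6, 0.2, 0.0]])
        g = combine_and_select(C, np.ones((3, 3)), k=1, mode="product")
        np.testing.assert_array_equal(g.neighbours[0], [1])

    def test_product_with_unit_age_reduces_to_euclidean_knn(self, rng):
        """With a == 1 everywhere (all ages equal, fixed bandwidth), the
        supervised selection is plain Euclidean k-NN."""
        X = rng.normal(size=(20, 5))
        A = image_similarity(X, bandwidth=2.0)
        a = age_similarity(np.full(20, 12.0), bandwidth=5.0)
        assert np.all(a.values == 1.0)
        M = A.values.copy()
        np.fill_diagonal(M, 0.0)
        g = combine_and_select(M, a, k=4, mode="product")
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        for i in range(20):
            np.fill_diagonal(d2, np.inf)
            knn = set(np.argsort(d2[i], kind="stable")[:4])
            assert set(g.neighbours[i]) == knn

    def test_zero_eligible_row_error_names_subject(self):
        M = np.zeros((3, 3))
        M[1, 2] = M[2, 1] = 0.5
        with pytest.raises(DataError, match="index 0"):
            combine_and_select(M, np.ones((3, 3)), k=1, mode="product")

    def test_short_row_flagged(self):
        M = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.9], [0.0, 0.9, 0.0]])
        g = combine_and_select(M, np.ones((3, 3)), k=2, mode="product")
        assert g.short_rows[0] and not g.short_rows[1]

    def test_weighted_sum_reapplies_masks(self):
        M = np.array([[0.0, 0.0, 0.4], [0.0, 0.0, 0.5], [0.4, 0.5, 0.0]])
        a = np.ones((3, 3))
        g = combine_and_select(M, a, k=2, mode="weighted_sum", weight=0.5)
        # pair (0,1) is masked in the image matrix: it must stay ineligible
        assert 1 not in g.neighbours[0]

    def test_product_mode_monotone_in_age_similarity(self, rng):
        """Increasing a_ij (others fixed) never evicts j from i's list."""
        n, k = 12, 3
        A = image_similarity(rng.normal(size=(n, 4)), bandwidth=2.0)
        M = apply_constraints(A, _table(list(range(3, 3 + n)), ["M"] * n,
                                        ["A"] * n))
        a = rng.uniform(0.1, 0.9, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        g0 = combine_and_select(M, a, k=k, mode="product")
        i, j = 2, g0.neighbours[2][0]
        a2 = a.copy()
        a2[i, j] = a2[j, i] = min(1.0, a[i, j] * 1.5)
        g1 = combine_and_select(M, a2, k=k, mode="product")
        assert j in g1.neighbours[i]


class TestGraphProperties:
    def _random_cohort(self, rng, n=25):
        ages = rng.uniform(3, 21, n)
        sexes = rng.choice(["F", "M"], n)
        sites = rng.choice(["A", "B", "C"], n)
        X = rng.normal(size=(n, 6))
        return _table(list(ages), list(sexes), list(sites)), X

    def test_masked_entries_never_selected(self, rng):
        """Exhaustive audit: every selected edge satisfies sex-match and
        site-mismatch, and nobody selects themselves."""
        for _ in range(5):
            table, X = self._random_cohort(rng)
            A = image_similarity(X, "auto")
            a = age_similarity(table, "auto")
            M = apply_constraints(A, table, use_site=True)
            g = combine_and_select(M, a, k=4, mode="product")
            sex, site = table.sex_code, table.site
            for i, nb in enumerate(g.neighbours):
                assert i not in nb
                for j in nb:
                    assert sex[j] == sex[i]
                    assert site[j] != site[i]

    def test_relabel_equivariance(self, rng):
        table, X = self._random_cohort(rng, n=18)
        perm = rng.permutation(18)
        table_p = table.iloc(perm)
        A = image_similarity(X, bandwidth=2.0)
        a = age_similarity(table, bandwidth=3.0)
        M = apply_constraints(A, table)
        g = combine_and_select(M, a, k=3, mode="product")
        A_p = image_similarity(X[perm], bandwidth=2.0)
        a_p = age_similarity(table_p, bandwidth=3.0)
        M_p = apply_constraints(A_p, table_p)
        g_p = combine_and_select(M_p, a_p, k=3, mode="product")
        inv = np.argsort(perm)
        for new_i, old_i in enumerate(perm):
            np.testing.assert_array_equal(np.sort(inv[g.neighbours[old_i]]),
                                          np.sort(g_p.neighbours[new_i]))

    def test_neighbour_lists_are_sex_pure(self, rng):
        table, X = self._random_cohort(rng)
        A = image_similarity(X, "auto")
        a = age_similarity(table, "auto")
        M = apply_constraints(A, table)
        g = combine_and_select(M, a, k=5, mode="product")
        sex = table.sex_code
        for i, nb in enumerate(g.neighbours):
            assert np.all(sex[nb] == sex[i])


def test_edge_frame_export(rng):
    X = rng.normal(size=(6, 3))
    M = apply_constraints(image_similarity(X, 2.0),
                          _table([4, 5, 6, 7, 8, 9], ["M"] * 6, ["A"] * 6))
    g = combine_and_select(M, np.ones((6, 6)), k=2, mode="product")
    df = g.to_edge_frame([f"s{i}" for i in range(6)])
    assert list(df.columns) == ["subject_id", "neighbour_id", "rank",
                                "combined_score"]
    assert len(df) == 12
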