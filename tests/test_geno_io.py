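import numpy as np
import pytest

from sparselmm.geno_io import (
    GenotypeMatrix,
    Kinship,
    PhenotypeVector,
    compute_cross_kinship,
    compute_kinship,
    impute_and_center,
    read_bimbam_genotypes,
    read_kinship,
    read_phenotypes,
    write_bimbam_genotypes,
    write_kinship,
    write_phenotypes,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadBimbam:
    def test_transposed_matrix(self, tmp_path):
        path = _write(tmp_path, "g.txt",
                      "rs1, A, T, 1, 0, 2\nrs2, G, C, 0, 0, 0\n")
        g = read_bimbam_genotypes(path)
        assert g.marker_ids == ["rs1", "rs2"]
        assert g.allele_pair == [("A", "T"), ("G", "C")]
        np.testing.assert_array_equal(g.dosages, [[1, 0], [0, 0], [2, 0]])

    def test_na_sets_missing_mask(self, tmp_path):
        path = _write(tmp_path, "g.txt",
                      "rs1, A, T, 1, NA, 2\nrs2, G, C, 0, 0, 0\n")
        g = read_bimbam_genotypes(path)
        assert g.missing_mask.sum() == 1
        assert g.missing_mask[1, 0]

    def test_ragged_line_names_line_number(self, tmp_path):
        path = _write(tmp_path, "g.txt",
                      "rs1, A, T, 1, 0, 2\nrs2, G, C, 0, 0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bimbam_genotypes(path)

    def test_out_of_range_dosage(self, tmp_path):
        path = _write(tmp_path, "g.txt", "rs1, A, T, 1, 0, 2.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_bimbam_genotypes(path)

    def test_roundtrip_bit_exact(self, tmp_path, rng):
        raw = rng.uniform(0, 2, size=(7, 5))
        miss = rng.random((7, 5)) < 0.1
        g = GenotypeMatrix(raw, [f"m{j}" for j in range(5)],
                           missing_mask=miss)
        path = tmp_path / "rt.txt"
        write_bimbam_genotypes(g, path)
        g2 = read_bimbam_genotypes(path)
        np.testing.assert_array_equal(g2.missing_mask, miss)
        obs = ~miss
        np.testing.assert_array_equal(g2.dosages[obs], raw[obs])


class TestImputeAndCenter:
    def test_two_value_column(self):
        g = GenotypeMatrix(np.array([[0.0], [2.0]]), ["m0"])
        c = impute_and_center(g)
        np.testing.assert_allclose(c.dosages[:, 0], [-1, 1])
        assert c.col_vars[0] == pytest.approx(1.0)

    def test_monomorphic_column(self):
        g = GenotypeMatrix(np.ones((3, 1)), ["m0"])
        c = impute_and_center(g)
        np.testing.assert_allclose(c.dosages[:, 0], 0.0)
        assert c.col_vars[0] == 0.0

    def test_s_a_matches_bruteforce(self, rng):
        raw = rng.uniform(0, 2, size=(50, 20))
        c = impute_and_center(GenotypeMatrix(raw, [f"m{j}" for j in range(20)]))
        expected = []
        for j in range(20):
            col = raw[:, j] - raw[:, j].mean()
            expected.append(np.sum(col ** 2) / 50)
        assert c.s_a == pytest.approx(np.mean(expected), abs=1e-12)

    def test_missing_imputed_to_column_mean(self):
        raw = np.array([[0.0, 1], [2, 1], [0, 1]])
        miss = np.zeros((3, 2), dtype=bool)
        miss[0, 0] = True
        c = impute_and_center(GenotypeMatrix(raw, ["a", "b"], missing_mask=miss))
        # observed mean of col 0 is 1; imputed value 1 centers to 0
        assert c.dosages[0, 0] == pytest.approx(0.0)
        np.testing.assert_allclose(c.dosages.sum(axis=0), 0.0, atol=1e-12)

    def test_fully_missing_column_errors(self):
        miss = np.ones((3, 1), dtype=bool)
        g = GenotypeMatrix(np.zeros((3, 1)), ["badmarker"], missing_mask=miss)
        with pytest.raises(ValueError, match="badmarker"):
            impute_and_center(g)

    def test_columns_sum_to_zero(self, small_geno):
        np.testing.assert_allclose(
            small_geno.dosages.sum(axis=0), 0.0, atol=1e-8 * small_geno.n
        )


class TestComputeKinship:
    def test_two_by_two(self):
        g = GenotypeMatrix(np.array([[-1.0, 1], [1, -1]]), ["a", "b"],
                           centered=True)
        kin = compute_kinship(g)
        np.testing.assert_allclose(kin.K, [[1, -1], [-1, 1]])
        assert kin.s_b == pytest.approx(1.0)

    def test_all_zero(self):
        g = GenotypeMatrix(np.zeros((3, 2)), ["a", "b"], centered=True)
        kin = compute_kinship(g)
        np.testing.assert_array_equal(kin.K, 0.0)
        assert kin.s_b == 0.0

    def test_bruteforce_double_loop(self, rng):
        X = rng.standard_normal((30, 200))
        X -= X.mean(axis=0)
        g = GenotypeMatrix(X, [f"m{j}" for j in range(200)], centered=True)
        kin = compute_kinship(g)
        ref = np.empty((30, 30))
        for i in range(30):
            for j in range(30):
                ref[i, j] = sum(X[i, k] * X[j, k] for k in range(200)) / 200
        np.testing.assert_allclose(kin.K, ref, atol=1e-10)
        assert kin.eigenvalues.min() >= 0

    def test_zero_markers_errors(self):
        g = GenotypeMatrix(np.zeros((3, 0)), [], centered=True)
        with pytest.raises(ValueError):
            compute_kinship(g)

    def test_marker_permutation_invariance(self, small_geno):
        k1 = compute_kinship(small_geno)
        perm = np.random.default_rng(0).permutation(small_geno.p)
        g2 = GenotypeMatrix(small_geno.dosages[:, perm],
                            [small_geno.marker_ids[j] for j in perm],
                            centered=True)
        k2 = compute_kinship(g2)
        np.testing.assert_allclose(k1.K, k2.K, atol=1e-12)

    def test_individual_permutation_equivariance(self, small_geno):
        k1 = compute_kinship(small_geno)
        perm = np.random.default_rng(1).permutation(small_geno.n)
        g2 = GenotypeMatrix(small_geno.dosages[perm], small_geno.marker_ids,
                            centered=True)
        k2 = compute_kinship(g2)
        np.testing.assert_allclose(k2.K, k1.K[np.ix_(perm, perm)], atol=1e-12)

    def test_quadratic_form_through_eigendecomposition(self, small_kinship, rng):
        v = rng.standard_normal(small_kinship.n)
        direct = v @ small_kinship.K @ v
        Utv = small_kinship.eigenvectors.T @ v
        via_eigen = np.sum(small_kinship.eigenvalues * Utv ** 2)
        assert via_eigen == pytest.approx(direct, abs=1e-8)

    def test_eigendecomposition_invariants(self, small_kinship):
        U = small_kinship.eigenvectors
        w = small_kinship.eigenvalues
        np.testing.assert_allclose(U.T @ U, np.eye(small_kinship.n), atol=1e-8)
        np.testing.assert_allclose(U @ np.diag(w) @ U.T, small_kinship.K,
                                   atol=1e-6)
        assert np.all(np.diff(w) <= 1e-12)  # descending


class TestReadKinship:
    def test_identity(self, tmp_path):
        path = _write(tmp_path, "k.txt", "1 0\n0 1\n")
        kin = read_kinship(path, 2)
        np.testing.assert_array_equal(kin.K, np.eye(2))
        assert kin.s_b == 1.0
        np.testing.assert_allclose(kin.eigenvalues, 1.0)

    def test_roundtrip(self, tmp_path, small_geno):
        kin = compute_kinship(small_geno)
        path = tmp_path / "k.txt"
        write_kinship(kin, path)
        kin2 = read_kinship(path, small_geno.n)
        np.testing.assert_allclose(kin2.K, kin.K, atol=1e-10)

    def test_dimension_error(self, tmp_path):
        path = _write(tmp_path, "k.txt", "1 0 0\n0 1 0\n")
        with pytest.raises(ValueError, match="2x3"):
            read_kinship(path, 2)

    def test_asymmetry_error(self, tmp_path):
        path = _write(tmp_path, "k.txt", "1 0.5\n0 1\n")
        with pytest.raises(ValueError, match="asymmetry"):
            read_kinship(path, 2)


class TestPhenotypes:
    def test_read_with_missing(self, tmp_path):
        path = _write(tmp_path, "y.txt", "1.5\nNA\n-0.25\n")
        y = read_phenotypes(path)
        np.testing.assert_array_equal(y.missing_mask, [False, True, False])
        assert y.values[0] == 1.5
        np.testing.assert_array_equal(y.observed_idx, [0, 2])

    def test_binary_detection(self, tmp_path):
        path = _write(tmp_path, "y.txt", "1\n0\nNA\n1\n")
        assert read_phenotypes(path).is_binary
        path2 = _write(tmp_path, "y2.txt", "1\n0.5\n")
        assert not read_phenotypes(path2).is_binary

    def test_roundtrip(self, tmp_path, rng):
        y = PhenotypeVector(values=rng.standard_normal(9))
        path = tmp_path / "y.txt"
        write_phenotypes(y, path)
        y2 = read_phenotypes(path)
        np.testing.assert_array_equal(y2.values, y.values)


class TestCrossKinship:
    def test_matches_block_of_joint_kinship(self, rng):
        raw = rng.integers(0, 3, size=(20, 15)).astype(float)
        g = impute_and_center(GenotypeMatrix(raw, [f"m{j}" for j in range(15)]))
        kin = compute_kinship(g)
        tr, te = np.arange(12), np.arange(12, 20)
        kc = compute_cross_kinship(g.subset_individuals(te),
                                   g.subset_individuals(tr))
        np.testing.assert_allclose(kc, kin.K[np.ix_(te, tr)], atol=1e-12)

    def test_marker_mismatch_errors(self, small_geno):
        other = GenotypeMatrix(small_geno.dosages,
                               [f"x{j}" for j in range(small_geno.p)],
                               centered=True)
        with pytest.raises(ValueError, match="mismatch"):
            compute_cross_kinship(other, small_geno)


class TestPlainMatrix:
    def test_roundtrip_with_missing(self, tmp_path, rng):
        from sparselmm.geno_io import read_plain_genotypes, write_plain_genotypes
        raw = rng.uniform(0, 2, size=(6, 4))
        miss = rng.random((6, 4)) < 0.2
        g = GenotypeMatrix(raw, ["a", "b", "c", "d"], missing_mask=miss)
        path = tmp_path / "m.txt"
        write_plain_genotypes(g, path)
        g2 = read_plain_genotypes(path, marker_ids=["a", "b", "c", "d"])
        np.testing.assert_array_equal(g2.missing_mask, miss)
        np.testing.assert_array_equal(g2.dosages[~miss], raw[~miss])

    def test_default_marker_ids(self, tmp_path):
        from sparselmm.geno_io import read_plain_genotypes
        path = tmp_path / "m.txt"
        path.write_text("0 1 2\n2 1 0\n")
        g = read_plain_genotypes(path)
        assert g.marker_ids == ["m0", "m1", "m2"]
        assert g.dosages.shape == (2, 3)


class TestStandardize:
    def test_unit_variance_columns(self, rng):
        raw = rng.integers(0, 3, size=(40, 6)).astype(float)
        c = impute_and_center(GenotypeMatrix(raw, [f"m{j}" for j in range(6)]),
                              standardize=True)
        np.testing.assert_allclose(c.col_vars, 1.0, atol=1e-10)
        assert c.s_a == pytest.approx(1.0)

    def test_monomorphic_column_left_at_zero(self):
        raw = np.column_stack([np.ones(5), np.arange(5.0) % 3])
        c = impute_and_center(GenotypeMatrix(raw, ["mono", "poly"]),
                              standardize=True)
        np.testing.assert_allclose(c.dosages[:, 0], 0.0)
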