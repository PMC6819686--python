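"""Genotype QC, VanRaden G, blending and the H-inverse block."""

import numpy as np
import pytest

import sgeblup as sg
from sgeblup.genomic import GenotypeError, QCThresholds, hwe_pvalues


def disabled_thresholds():
    return QCThresholds(
        min_maf=None, max_marker_missing=None, max_animal_missing=None,
        hwe_alpha=None, drop_monomorphic=False, drop_nonautosomal=False,
    )


class TestQC:
    def test_monomorphic_removed(self):
        X = np.column_stack([np.full(20, 2.0), np.tile([0.0, 1.0], 10)])
        _, _, kept, report = sg.qc_filter(X, QCThresholds(hwe_alpha=None))
        assert list(kept) == [1]
        assert report.markers_removed["monomorphic"] == 1

    def test_disabled_thresholds_identity(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        out, animals, markers, _ = sg.qc_filter(X, disabled_thresholds())
        np.testing.assert_array_equal(out, X)
        assert len(animals) == 30 and len(markers) == 10

    def test_planted_missing_markers_removed(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(100, 50)).astype(float)
        planted = [3, 11, 24, 38, 49]
        X[:, planted] = np.nan
        thr = QCThresholds(min_maf=None, hwe_alpha=None, max_marker_missing=0.1,
                           max_animal_missing=None, drop_monomorphic=False)
        _, _, kept, report = sg.qc_filter(X, thr)
        assert sorted(set(range(50)) - set(kept)) == planted
        assert report.markers_removed["missingness"] == 5

    def test_animal_missingness_rule(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(10, 20)).astype(float)
        X[4, :15] = np.nan  # 75% missing
        thr = QCThresholds(min_maf=None, hwe_alpha=None, max_marker_missing=None,
                           max_animal_missing=0.5, drop_monomorphic=False)
        _, animals, _, report = sg.qc_filter(X, thr)
        assert 4 not in animals
        assert report.animals_removed["missingness"] == 1

    def test_hwe_planted_violation(self):
        # all heterozygotes: chi-square p is tiny at n=200
        X = np.column_stack([np.ones(200), np.repeat([0.0, 1.0, 2.0], [50, 100, 50])])
        thr = QCThresholds(min_maf=None, max_marker_missing=None,
                           max_animal_missing=None, hwe_alpha=1e-6,
                           drop_monomorphic=False)
        _, _, kept, report = sg.qc_filter(X, thr)
        assert list(kept) == [1]
        assert report.markers_removed["hwe"] == 1

    def test_nonautosomal_rule(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(40, 4)).astype(float)
        chroms = np.array(["1", "X", "2", "MT"])
        _, _, kept, report = sg.qc_filter(
            X, disabled_thresholds().__class__(
                min_maf=None, max_marker_missing=None, max_animal_missing=None,
                hwe_alpha=None, drop_monomorphic=False, drop_nonautosomal=True),
            chromosomes=chroms,
        )
        assert list(kept) == [0, 2]
        assert report.markers_removed["nonautosomal"] == 2

    def test_everything_removed_raises(self):
        X = np.full((10, 3), 2.0)
        with pytest.raises(GenotypeError, match="every marker"):
            sg.qc_filter(X, QCThresholds())


class TestAlleleFrequencies:
    def test_hand_counts(self):
        X = np.array([[0.0, 2.0], [1.0, 2.0], [2.0, np.nan]])
        np.testing.assert_allclose(sg.allele_frequencies(X), [0.5, 1.0])

    def test_all_missing_marker_raises(self):
        X = np.array([[np.nan], [np.nan]])
        with pytest.raises(GenotypeError):
            sg.allele_frequencies(X)

    def test_hwe_pvalue_uniform_marker(self):
        # genotype counts exactly at HWE expectation -> chi2 = 0, p = 1
        X = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None]
        assert hwe_pvalues(X)[0] == pytest.approx(1.0)


class TestG:
    def test_two_animal_hand_example(self):
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        G = sg.build_G(X, np.array([0.5, 0.5]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_animals_identical(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(10, 40)).astype(float)
        X[5] = X[2]
        G = sg.build_G(X)
        np.testing.assert_allclose(G[2], G[5])
        assert G[2, 5] == pytest.approx(G[2, 2])

    def test_missing_dosages_rejected(self):
        with pytest.raises(GenotypeError, match="impute"):
            sg.build_G(np.array([[np.nan, 1.0], [0.0, 2.0]]))

    def test_impute_mean_fills_2p(self):
        X = np.array([[0.0, 2.0], [2.0, np.nan]])
        out = sg.impute_mean(X)
        assert out[1, 1] == pytest.approx(2.0)  # p = 1 -> fill 2p = 2

    def test_gene_dropped_G_tracks_A22(self, small_dataset):
        """Mean G off-diagonal approximates mean pedigree relationship when
        founder allele frequencies are used for centering."""
        ds = small_dataset
        ids = ds.genotypes.index.to_numpy()
        G = sg.build_G(ds.genotypes.to_numpy(dtype=float), ds.founder_freqs)
        A22 = sg.build_A22(ds.pedigree, ids)
        iu = np.triu_indices_from(G, k=1)
        assert abs(G[iu].mean() - A22[iu].mean()) < 0.05
        assert sg.g_a22_offdiag_correlation(G, A22) > 0.5


class TestBlend:
    def test_limits(self):
        G = np.array([[2.0, -2.0], [-2.0, 2.0]])
        A = np.eye(2)
        np.testing.assert_allclose(sg.blend_G(G, A, 1.0, 0.0), G)
        np.testing.assert_allclose(sg.blend_G(G, A, 0.0, 1.0), A)
        np.testing.assert_allclose(
            sg.blend_G(G, A, 0.95, 0.05), [[1.95, -1.9], [-1.9, 1.95]]
        )

    def test_shape_and_weight_errors(self):
        with pytest.raises(ValueError, match="shape"):
            sg.blend_G(np.eye(2), np.eye(3))
        with pytest.raises(ValueError, match="sum to 1"):
            sg.blend_G(np.eye(2), np.eye(2), 0.9, 0.2)


class TestHInverse:
    def test_cancellation_identity(self, random_pedigree):
        """tau = omega = 1 with G_b = A22 gives H-inverse = A-inverse."""
        ids = list(random_pedigree.ids[50:80])
        A22 = sg.build_A22(random_pedigree, ids)
        A_inv = sg.build_A_inverse(random_pedigree)
        H_inv = sg.build_H_inverse(
            A_inv, A22, A22, 1.0, 1.0, random_pedigree.indices_of(ids)
        )
        assert abs(H_inv - A_inv).max() < 1e-8

    def test_no_genotyped_animals(self, random_pedigree):
        A_inv = sg.build_A_inverse(random_pedigree)
        H_inv = sg.build_H_inverse(A_inv, np.empty((0, 0)), np.empty((0, 0)),
                                   1.0, 0.6, np.array([], dtype=int))
        assert abs(H_inv - A_inv).max() == 0.0

    def test_block_matches_dense_oracle(self, small_dataset):
        ds = small_dataset
        ids = ds.genotypes.index.to_numpy()
        gix = ds.pedigree.indices_of(ids)
        A22 = sg.build_A22(ds.pedigree, ids)
        G = sg.build_G(sg.impute_mean(ds.genotypes.to_numpy(dtype=float)))
        G_b = sg.blend_G(G, A22)
        A_inv = sg.build_A_inverse(ds.pedigree)
        H_inv = sg.build_H_inverse(A_inv, A22, G_b, 1.0, 0.6, gix)
        block = (H_inv - A_inv).toarray()[np.ix_(gix, gix)]
        dense = np.linalg.inv(G_b) - 0.6 * np.linalg.inv(A22)
        np.testing.assert_allclose(block, dense, atol=1e-8)

    def test_linear_in_omega(self, small_dataset):
        """H-inv(omega1) - H-inv(omega2) = (omega2 - omega1) A22-inv on the block."""
        ds = small_dataset
        ids = ds.genotypes.index.to_numpy()
        gix = ds.pedigree.indices_of(ids)
        A22 = sg.build_A22(ds.pedigree, ids)
        G = sg.build_G(sg.impute_mean(ds.genotypes.to_numpy(dtype=float)))
        G_b = sg.blend_G(G, A22)
        A_inv = sg.build_A_inverse(ds.pedigree)
        H1 = sg.build_H_inverse(A_inv, A22, G_b, 1.0, 0.3, gix)
        H2 = sg.build_H_inverse(A_inv, A22, G_b, 1.0, 0.9, gix)
        diff = (H1 - H2).toarray()
        outside = diff.copy()
        outside[np.ix_(gix, gix)] = 0.0
        assert abs(outside).max() < 1e-10
        np.testing.assert_allclose(
            diff[np.ix_(gix, gix)], (0.9 - 0.3) * np.linalg.inv(A22), atol=1e-8
        )

    @pytest.mark.parametrize("omega", [0.1, 0.4, 0.7, 1.0])
    def test_symmetric_across_omega_grid(self, small_dataset, omega):
        ds = small_dataset
        ids = ds.genotypes.index.to_numpy()
        A22 = sg.build_A22(ds.pedigree, ids)
        G = sg.build_G(sg.impute_mean(ds.genotypes.to_numpy(dtype=float)))
        G_b = sg.blend_G(G, A22)
        A_inv = sg.build_A_inverse(ds.pedigree)
        H = sg.build_H_inverse(A_inv, A22, G_b, 1.0, omega,
                               ds.pedigree.indices_of(ids))
        assert abs(H - H.T).max() < 1e-10


class TestOffdiagCorrelation:
    def test_identical_matrices(self):
        M = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        assert sg.g_a22_offdiag_correlation(M, M) == pytest.approx(1.0)

    def test_constant_offdiagonal_undefined(self):
        G = np.array([[1.0, 0.3], [0.3, 1.0]])
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="constant"):
            sg.g_a22_offdiag_correlation(G, A)


def test_assemble_relationships_end_to_end(small_dataset):
    """The one-call chain produces a coherent RelationshipSet."""
    ds = small_dataset
    rs = sg.assemble_relationships(ds.pedigree, ds.genotypes, tau=1.0, omega=0.7)
    assert rs.G.shape == rs.A22.shape == rs.G_b.shape
    np.testing.assert_allclose(rs.G_b, 0.95 * rs.G + 0.05 * rs.A22)
    assert rs.H_inv.shape[0] == len(ds.pedigree)
    gix = ds.pedigree.indices_of(rs.genotyped_ids)
    block = (rs.H_inv - sg.build_A_inverse(ds.pedigree)).toarray()[np.ix_(gix, gix)]
    dense = np.linalg.inv(rs.G_b) - 0.7 * np.linalg.inv(rs.A22)
    np.testing.assert_allclose(block, dense, atol=1e-8)
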