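import numpy as np
import pytest
from shapely import Polygon

from stylemorph.efa import compute_efa, normalize
from stylemorph.morphospace import (
    MorphospaceEmbedding,
    assemble_matrix,
    effective_components,
    pca,
    shape_along_pc,
)
from stylemorph.synthetic import GroupSpec, ShapeParams, generate_dataset


@pytest.fixture(scope="module")
def coeff_bank():
    groups = [
        GroupSpec("a", 25, ShapeParams(),
                  {"posterior_rim_curvature": 0.1, "stylet_rel_length": 0.12,
                   "stylet_thickness": 0.02}),
    ]
    ds = generate_dataset(groups, 128, seed=5)
    return [normalize(compute_efa(o, 20)) for o in ds.outlines]


class TestAssembleMatrix:
    def test_column_count_drops_normalization_constants(self, coeff_bank):
        M, cols = assemble_matrix(coeff_bank)
        assert M.shape == (25, 4 * 20 - 3)
        assert cols[0] == "d1"
        assert "a1" not in cols and "b1" not in cols and "c1" not in cols

    def test_identical_specimens_identical_rows(self, coeff_bank):
        M, _ = assemble_matrix([coeff_bank[0], coeff_bank[0]] + coeff_bank[1:])
        np.testing.assert_array_equal(M[0], M[1])

    def test_unnormalized_input_rejected(self):
        from stylemorph.efa import EFACoefficients

        raw = EFACoefficients([1.0, 0.1], [0.2, 0.0], [0.1, 0.0], [0.8, 0.0])
        with pytest.raises(ValueError, match="not normalized"):
            assemble_matrix([raw])

    def test_mixed_harmonic_counts_rejected(self, coeff_bank):
        from stylemorph.efa import EFACoefficients

        short = EFACoefficients([1.0], [0.0], [0.0], [0.5], normalized=True)
        with pytest.raises(ValueError, match="mixed"):
            assemble_matrix(coeff_bank + [short])


class TestPCA:
    def test_proportions_sum_to_one(self, coeff_bank):
        M, cols = assemble_matrix(coeff_bank)
        emb = pca(M, cols)
        assert emb.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-15)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(50, 10))
        emb = pca(X)
        # independent oracle: scikit-learn PCA
        from sklearn.decomposition import PCA as SkPCA

        ref = SkPCA(n_components=10).fit_transform(X)
        for j in range(emb.scores.shape[1]):
            col = emb.scores[:, j]
            assert (
                np.abs(col - ref[:, j]).max() < 1e-8
                or np.abs(col + ref[:, j]).max() < 1e-8
            )

    def test_eigenvalue_sum_equals_total_variance(self, coeff_bank):
        M, cols = assemble_matrix(coeff_bank)
        emb = pca(M, cols)
        total = np.var(M, axis=0, ddof=1).sum()
        assert emb.eigenvalues.sum() == pytest.approx(total, abs=1e-9)

    def test_scores_uncorrelated(self, coeff_bank):
        M, cols = assemble_matrix(coeff_bank)
        emb = pca(M, cols)
        k = emb.effective_k
        C = np.cov(emb.scores[:, :k].T)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_from_all_components(self, rng):
        X = rng.normal(size=(30, 8))
        emb = pca(X)
        Xc = X - X.mean(axis=0)
        back = emb.scores @ emb.loadings.T
        assert np.abs(back - Xc).max() < 1e-8

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 6))
        perm = rng.permutation(40)
        a = pca(X)
        b = pca(X[perm])
        for j in range(len(a.eigenvalues)):
            assert (
                np.abs(a.scores[perm, j] - b.scores[:, j]).max() < 1e-8
                or np.abs(a.scores[perm, j] + b.scores[:, j]).max() < 1e-8
            )

    def test_collinear_cloud_single_component(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t])
        emb = pca(X)
        assert len(emb.eigenvalues) == 1
        assert emb.proportions[0] == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="3 rows"):
            pca(rng.normal(size=(2, 4)))
        with pytest.raises(ValueError, match="rank-0"):
            pca(np.ones((5, 3)))
        X = rng.normal(size=(5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca(X)


def _dummy_embedding(eigenvalues):
    lam = np.asarray(eigenvalues, float)
    return MorphospaceEmbedding(
        scores=np.zeros((3, len(lam))), eigenvalues=lam,
        proportions=lam / lam.sum(), loadings=np.eye(len(lam)),
        mean_vector=np.zeros(len(lam)), columns=[f"c{i}" for i in range(len(lam))],
        specimen_ids=["a", "b", "c"], groups=["", "", ""],
    )


class TestEffectiveComponents:
    def test_mean_eigenvalue_rule(self):
        emb = _dummy_embedding([5.0, 3.0, 1.0, 0.5, 0.5])
        assert effective_components(emb) == 2  # mean eigenvalue = 2

    def test_all_equal_falls_back_with_warning(self):
        emb = _dummy_embedding([1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="falling back"):
            assert effective_components(emb) == 2


@pytest.fixture(scope="module")
def thickness_embedding():
    """Morphospace driven by a single stylet-thickness factor."""
    groups = [GroupSpec("g", 30, ShapeParams(), {"stylet_thickness": 0.03})]
    ds = generate_dataset(groups, 128, seed=11)
    coeffs = [normalize(compute_efa(o, 16)) for o in ds.outlines]
    M, cols = assemble_matrix(coeffs)
    return pca(M, cols)


class TestShapeAlongPC:
    def test_zero_multiplier_returns_mean_shape(self, thickness_embedding):
        a = shape_along_pc(thickness_embedding, 1, 0.0)
        b = shape_along_pc(thickness_embedding, 2, 0.0)
        np.testing.assert_allclose(a.points, b.points, atol=1e-12)

    def test_thickness_pc_renders_differ_in_enclosed_area(self, thickness_embedding):
        plus = shape_along_pc(thickness_embedding, 1, 2.0)
        minus = shape_along_pc(thickness_embedding, 1, -2.0)
        area_plus = Polygon(plus.closed_points()).area
        area_minus = Polygon(minus.closed_points()).area
        # thicker stylets enclose more area in the normalized frame; the
        # loading sign convention fixes which extreme is the thick one
        assert abs(area_plus - area_minus) / max(area_plus, area_minus) > 0.02

    def test_out_of_range_pc_rejected(self, thickness_embedding):
        with pytest.raises(ValueError, match="out of range"):
            shape_along_pc(thickness_embedding, 99, 1.0)
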