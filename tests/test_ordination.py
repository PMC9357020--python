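"""PCA, Mahalanobis distances, CVA and permutation tests."""
import numpy as np
import pytest

from conglobe.errors import DimensionalityError, InsufficientDataError
from conglobe.ordination import (
    CVAResult,
    cva,
    mahalanobis_matrix,
    pc_deformation,
    pca,
    pca_matrix,
    permutation_test,
    point_to_group_distances,
    pooled_within_covariance,
)
from conglobe.superimposition import gpa


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 6)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
    res = pca_matrix(x)
    vals = np.linalg.eigvalsh(np.cov(x, rowvar=False))[::-1]
    np.testing.assert_allclose(res.eigenvalues, vals[: res.n_components], atol=1e-10)
    # axes orthonormal, scores centred, reconstruction exact in retained space
    np.testing.assert_allclose(res.axes @ res.axes.T, np.eye(res.n_components), atol=1e-10)
    np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(res.mean + res.scores @ res.axes, x, atol=1e-8)


def test_pca_scores_variance_equals_eigenvalues():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(40, 5))
    res = pca_matrix(x)
    np.testing.assert_allclose(res.scores.var(axis=0, ddof=1), res.eigenvalues, atol=1e-10)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(20, 4))
    a, b = pca_matrix(x), pca_matrix(x.copy())
    np.testing.assert_allclose(a.axes, b.axes)
    for row in a.axes:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_drops_null_directions():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=(25, 2))
    basis = np.linalg.qr(rng.normal(size=(6, 2)))[0]
    x = scores @ basis.T  # rank 2 in 6-d
    res = pca_matrix(x)
    assert res.n_components == 2


def test_pca_project_round_trip():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(15, 4))
    res = pca_matrix(x)
    np.testing.assert_allclose(res.project(x), res.scores, atol=1e-10)


def test_pca_needs_three_specimens():
    with pytest.raises(InsufficientDataError):
        pca_matrix(np.zeros((2, 4)))


def test_pca_on_aligned_dataset_and_deformation():
    rng = np.random.default_rng(6)
    aligned = gpa(rng.normal(size=(10, 8, 2)))
    res = pca(aligned)
    assert res.n_landmarks == 8
    shape = pc_deformation(res, 0, 0.1)
    assert shape.shape == (8, 2)
    np.testing.assert_allclose(
        shape.reshape(-1), res.mean + 0.1 * res.axes[0], atol=1e-12
    )
    with pytest.raises(IndexError):
        pc_deformation(res, res.n_components, 1.0)


# ---------------------------------------------------------------------------
# Mahalanobis machinery
# ---------------------------------------------------------------------------


def test_pooled_within_covariance_hand_example():
    x = np.array([[0.0], [2.0], [10.0], [14.0]])
    labels = np.array(["a", "a", "b", "b"])
    # within-group scatter: (1^2+1^2) + (2^2+2^2) = 10; divisor n-g = 2
    cov = pooled_within_covariance(x, labels)
    assert cov[0, 0] == pytest.approx(5.0)


def test_mahalanobis_matches_direct_formula():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(40, 3))
    x[20:] += [2.0, 0.0, -1.0]
    labels = np.array(["g1"] * 20 + ["g2"] * 20)
    names, d = mahalanobis_matrix(x, labels, subspace_dim=3)
    cov = pooled_within_covariance(x, labels)
    diff = x[:20].mean(0) - x[20:].mean(0)
    expected = float(np.sqrt(diff @ np.linalg.inv(cov) @ diff))
    assert names == ["g1", "g2"]
    assert d[0, 1] == pytest.approx(expected, abs=1e-10)
    assert d[1, 0] == d[0, 1] and d[0, 0] == 0.0


def test_mahalanobis_invariant_to_affine_transform():
    """Full-rank Mahalanobis distance is invariant to invertible linear maps."""
    rng = np.random.default_rng(9)
    x = rng.normal(size=(30, 3))
    x[15:] += 1.0
    labels = np.array(["a"] * 15 + ["b"] * 15)
    _, d1 = mahalanobis_matrix(x, labels, subspace_dim=3)
    a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    _, d2 = mahalanobis_matrix(x @ a, labels, subspace_dim=3)
    assert d1[0, 1] == pytest.approx(d2[0, 1], rel=1e-8)


def test_subspace_cap_defaults_to_n_minus_g():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(12, 50))  # p >> n
    labels = np.array(["a"] * 6 + ["b"] * 6)
    names, d = mahalanobis_matrix(x, labels)  # must not fail despite p = 50
    assert np.isfinite(d).all()


def test_point_to_group_distances_matches_matrix_means():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(20, 4))
    labels = np.array(["a"] * 10 + ["b"] * 10)
    d = point_to_group_distances(x[:10].mean(0), x, labels, subspace_dim=4)
    assert d["a"] == pytest.approx(0.0, abs=1e-10)
    _, mat = mahalanobis_matrix(x, labels, subspace_dim=4)
    assert d["b"] == pytest.approx(mat[0, 1], abs=1e-10)


def test_mahalanobis_requires_two_per_group():
    x = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(InsufficientDataError):
        mahalanobis_matrix(x, np.array(["a", "a", "a", "a", "b"]))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _mean_diff(x, labels):
    """Toy pairwise statistic: absolute difference of group means (1-d x)."""
    names = sorted(set(labels.tolist()))
    m = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = x[labels == names[i]].mean()
            b = x[labels == names[j]].mean()
            m[i, j] = m[j, i] = abs(a - b)
    return names, m


def test_permutation_p_bounds_and_determinism():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(12, 1))
    labels = np.array(["a"] * 6 + ["b"] * 6)
    p1 = permutation_test(_mean_diff, x, labels, n_rounds=99, seed=1)
    p2 = permutation_test(_mean_diff, x, labels, n_rounds=99, seed=1)
    assert p1 == p2
    p = p1[("a", "b")]
    assert 1 / 100 <= p <= 1.0


def test_permutation_detects_complete_separation():
    x = np.concatenate([np.zeros(8), np.ones(8)]).reshape(-1, 1)
    x += np.random.default_rng(0).normal(0, 0.01, x.shape)
    labels = np.array(["a"] * 8 + ["b"] * 8)
    p = permutation_test(_mean_diff, x, labels, n_rounds=999, seed=2)
    assert p[("a", "b")] == pytest.approx(1 / 1000)


def test_exact_permutation_matches_hand_enumeration():
    # 2+2 design: 4!/(2!2!) = 6 distinct arrangements; statistic |mean diff|
    x = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array(["a", "a", "b", "b"])
    p = permutation_test(_mean_diff, x, labels, exact=True)
    # observed |diff| = 10; only the identity and the full swap reach 10
    assert p[("a", "b")] == pytest.approx(2 / 6)


def test_exact_permutation_identity_included_p_positive():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(6, 1))
    labels = np.array(["a"] * 3 + ["b"] * 3)
    p = permutation_test(_mean_diff, x, labels, exact=True)
    assert p[("a", "b")] >= 1 / 20  # 6!/(3!3!) = 20 arrangements


def test_permutation_rejects_bad_rounds():
    with pytest.raises(ValueError):
        permutation_test(_mean_diff, np.zeros((4, 1)), ["a", "a", "b", "b"], n_rounds=0)


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------


@pytest.fixture
def three_groups():
    rng = np.random.default_rng(14)
    x = rng.normal(size=(30, 4), scale=0.3)
    x[:10] += [0, 0, 0, 0]
    x[10:20] += [3, 0, 0, 0]
    x[20:] += [0, 3, 0, 0]
    labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    return x, labels


def test_cva_axes_capped_at_g_minus_1(three_groups):
    x, labels = three_groups
    res = cva(x, labels, n_permutations=0)
    assert isinstance(res, CVAResult)
    assert res.canonical_axes.shape[0] <= 2
    assert res.scores.shape == (30, res.canonical_axes.shape[0])


def test_cva_scores_separate_groups(three_groups):
    x, labels = three_groups
    res = cva(x, labels, n_permutations=0)
    # group means in canonical space are pairwise farther apart than within-sd
    means = {g: res.scores[labels == g].mean(0) for g in "abc"}
    within = max(res.scores[labels == g].std(axis=0).max() for g in "abc")
    for g1 in "abc":
        for g2 in "abc":
            if g1 < g2:
                assert np.linalg.norm(means[g1] - means[g2]) > 3 * within


def test_cva_p_values_significant_and_symmetric(three_groups):
    x, labels = three_groups
    res = cva(x, labels, n_permutations=199, seed=0)
    assert all(p == pytest.approx(1 / 200) for p in res.permutation_p.values())
    pm = res.p_matrix()
    np.testing.assert_allclose(pm, pm.T)
    assert np.isnan(np.diag(pm)).all()


def test_cva_row_space_reduction_preserves_distances(three_groups):
    """p >> n path must give the same Mahalanobis distances and p-values."""
    x, labels = three_groups
    rng = np.random.default_rng(15)
    basis = np.linalg.qr(rng.normal(size=(100, 4)))[0]
    wide = x @ basis.T  # isometric embedding into 100-d
    res_narrow = cva(x, labels, n_permutations=49, seed=3)
    res_wide = cva(wide, labels, n_permutations=49, seed=3)
    np.testing.assert_allclose(
        res_wide.pairwise_mahalanobis, res_narrow.pairwise_mahalanobis, atol=1e-6
    )
    assert res_wide.permutation_p == res_narrow.permutation_p


def test_cva_needs_labels():
    rng = np.random.default_rng(16)
    aligned = gpa(rng.normal(size=(6, 5, 2)))
    with pytest.raises(InsufficientDataError):
        cva(aligned)


def test_cva_subspace_dim_respected(three_groups):
    x, labels = three_groups
    res = cva(x, labels, subspace_dim=2, n_permutations=0)
    assert res.subspace_dim == 2
    with pytest.raises(DimensionalityError):
        cva(np.zeros((6, 3)) + np.eye(6, 3), ["a", "a", "a", "b", "b", "b"],
            subspace_dim=0, n_permutations=0)
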