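"""RV coefficient, similarity matrix, spectral bisection and the 63-module
hierarchy."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from facemod import segment
from facemod.segment import (
    ModuleTree,
    hierarchical_segment,
    landmark_rv_matrix,
    rv_coefficient,
    segment_similarity,
    spectral_bisect,
)


class TestRvCoefficient:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=(50, 4))
        assert np.isclose(rv_coefficient(x, x), 1.0, atol=1e-12)

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(60, 5))
        rot = special_ortho_group.rvs(5, random_state=rng)
        assert np.isclose(rv_coefficient(x, x @ rot), 1.0, atol=1e-10)
        y = rng.normal(size=(60, 3))
        r3 = special_ortho_group.rvs(3, random_state=rng)
        assert np.isclose(
            rv_coefficient(x, y), rv_coefficient(x, y @ r3), atol=1e-10
        )

    def test_univariate_reduces_to_squared_pearson(self, rng):
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(size=80)
        rv = rv_coefficient(x[:, None], y[:, None])
        r = np.corrcoef(x, y)[0, 1]
        assert np.isclose(rv, r**2, atol=1e-12)

    def test_zero_variance_block_rejected(self, rng):
        x = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="zero-variance"):
            rv_coefficient(x, np.zeros((30, 2)))


class TestLandmarkRvMatrix:
    def test_symmetric_unit_diagonal_bounded(self, small_study):
        shapes = small_study.cohorts[0].configurations[:80]
        m = landmark_rv_matrix(shapes)
        assert np.allclose(m, m.T, atol=1e-10)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= -1e-10 and m.max() <= 1 + 1e-10

    def test_duplicated_landmark_entry_one(self, rng):
        shapes = rng.normal(size=(50, 6, 3))
        shapes[:, 3, :] = shapes[:, 1, :]
        m = landmark_rv_matrix(shapes)
        assert np.isclose(m[1, 3], 1.0, atol=1e-10)

    def test_matches_pairwise_rv(self, rng):
        shapes = rng.normal(size=(40, 5, 3))
        m = landmark_rv_matrix(shapes)
        for i in range(5):
            for j in range(i):
                assert np.isclose(
                    m[i, j], rv_coefficient(shapes[:, i, :], shapes[:, j, :]),
                    atol=1e-10,
                )

    def test_independent_landmarks_near_zero(self, rng):
        shapes = rng.normal(size=(1000, 10, 3))
        m = landmark_rv_matrix(shapes)
        off = m[~np.eye(10, dtype=bool)]
        assert off.mean() < 0.05


class TestSpectralBisect:
    def test_planted_blocks_recovered(self, rng):
        m = np.full((12, 12), 0.05)
        m[:5, :5] = 0.9
        m[5:, 5:] = 0.9
        np.fill_diagonal(m, 1.0)
        left, right = spectral_bisect(m)
        got = {tuple(left.tolist()), tuple(right.tolist())}
        assert got == {tuple(range(5)), tuple(range(5, 12))}

    def test_two_indices_split_into_singletons(self):
        left, right = spectral_bisect(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert len(left) == 1 and len(right) == 1

    def test_permutation_equivariance(self, rng):
        base = np.full((10, 10), 0.1)
        base[:4, :4] = 0.8
        base[4:, 4:] = 0.8
        np.fill_diagonal(base, 1.0)
        base += rng.uniform(0, 0.01, base.shape)
        base = 0.5 * (base + base.T)
        np.fill_diagonal(base, 1.0)
        l1, r1 = spectral_bisect(base)
        perm = rng.permutation(10)
        l2, r2 = spectral_bisect(base[np.ix_(perm, perm)])
        mapped = {frozenset(perm[l2].tolist()), frozenset(perm[r2].tolist())}
        assert mapped == {frozenset(l1.tolist()), frozenset(r1.tolist())}

    def test_min_size_enforced(self, rng):
        m = np.full((9, 9), 0.1)
        m[:2, :2] = 0.95  # natural split would peel off 2 indices
        np.fill_diagonal(m, 1.0)
        left, right = spectral_bisect(m, min_size=4)
        assert min(len(left), len(right)) >= 4

    def test_perfectly_covarying_pair_never_split(self):
        # indices 0 and 1 are tied (similarity 1); a balanced cut must keep them
        m = np.full((6, 6), 0.3)
        m[0, 1] = m[1, 0] = 1.0
        np.fill_diagonal(m, 1.0)
        left, right = spectral_bisect(m, min_size=3)
        side_of = {i: 0 for i in left.tolist()} | {i: 1 for i in right.tolist()}
        assert side_of[0] == side_of[1]


class TestHierarchicalSegment:
    def test_depth5_yields_63_modules(self, small_study):
        shapes = np.concatenate([c.configurations for c in small_study.cohorts])
        tree = hierarchical_segment(shapes, depth=5)
        assert len(tree) == 63
        assert tree.level_counts() == [1, 2, 4, 8, 16, 32]

    def test_depth0_single_module(self, small_study):
        shapes = small_study.cohorts[0].configurations
        tree = hierarchical_segment(shapes, depth=0)
        assert len(tree) == 1
        assert tree.get(1).size == shapes.shape[1]

    def test_levels_partition_landmarks(self, small_study):
        shapes = small_study.cohorts[0].configurations
        tree = hierarchical_segment(shapes, depth=4)
        for level in range(tree.depth + 1):
            merged = np.sort(
                np.concatenate([m.landmark_indices for m in tree.at_level(level)])
            )
            assert np.array_equal(merged, np.arange(shapes.shape[1]))

    def test_too_deep_rejected_with_hint(self, small_study):
        shapes = small_study.cohorts[0].configurations  # L = 64
        with pytest.raises(ValueError, match="lower the depth"):
            hierarchical_segment(shapes, depth=7)

    def test_two_block_covariance_recovered_at_level1(self, rng):
        """Rand index 1 on data simulated with two independent blocks."""
        n, l_half = 400, 10
        block1 = rng.normal(size=(n, 1, 1)) * rng.normal(size=(1, l_half, 3))
        block2 = rng.normal(size=(n, 1, 1)) * rng.normal(size=(1, l_half, 3))
        shapes = np.concatenate(
            [block1 + 0.1 * rng.normal(size=(n, l_half, 3)),
             block2 + 0.1 * rng.normal(size=(n, l_half, 3))], axis=1
        )
        tree = hierarchical_segment(shapes, depth=1)
        kids = tree.children(1)
        got = {frozenset(k.landmark_indices.tolist()) for k in kids}
        assert got == {frozenset(range(l_half)), frozenset(range(l_half, 2 * l_half))}

    def test_adjacency_mask_keeps_modules_contiguous_inputs(self, small_study):
        shapes = small_study.cohorts[0].configurations
        adj = segment.knn_adjacency(small_study.template.coordinates, k=10)
        tree = hierarchical_segment(shapes, depth=3, adjacency=adj)
        assert len(tree) == 15

    def test_deterministic(self, small_study):
        shapes = small_study.cohorts[0].configurations
        t1 = hierarchical_segment(shapes, depth=3)
        t2 = hierarchical_segment(shapes, depth=3)
        for a, b in zip(t1.modules, t2.modules):
            assert np.array_equal(a.landmark_indices, b.landmark_indices)


def test_module_tree_tsv_round_trip(tmp_path, small_study):
    shapes = small_study.cohorts[0].configurations
    tree = hierarchical_segment(shapes, depth=3)
    path = tmp_path / "tree.tsv"
    tree.to_tsv(path)
    back = ModuleTree.from_tsv(path)
    assert len(back) == len(tree)
    for a, b in zip(tree.modules, back.modules):
        assert a.module_id == b.module_id and a.parent_id == b.parent_id
        assert np.array_equal(a.landmark_indices, b.landmark_indices)
    back.validate()


def test_segment_similarity_validates_tree(rng):
    s = rng.uniform(0.2, 0.8, (32, 32))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    tree = segment_similarity(s, depth=3, min_size=2)
    tree.validate()
    assert all(m.size >= 2 for m in tree.at_level(3))
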