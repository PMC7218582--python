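import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbqc.diversity import (
    DistanceMatrix,
    bray_curtis,
    complete_linkage,
    cut,
    distance_matrix,
    pcoa,
    permanova,
)
from lbqc.io import ProportionTable


def _dm(ids, mat):
    return DistanceMatrix(tuple(ids), np.asarray(mat, dtype=float))


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0], [0, 1]) == 1.0

    def test_known_value(self):
        assert bray_curtis([2, 0, 1], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=10),
        st.lists(st.floats(0, 1), min_size=2, max_size=10),
    )
    def test_symmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        x, y = np.array(a[:n]), np.array(b[:n])
        if (x + y).sum() == 0:
            return
        d = bray_curtis(x, y)
        assert d == bray_curtis(y, x)
        assert -1e-12 <= d <= 1 + 1e-12


class TestPCoA:
    def test_two_points_at_distance_two(self):
        res = pcoa(_dm(["a", "b"], [[0, 2], [2, 0]]))
        axis1 = res.coordinates[:, 0]
        assert sorted(axis1) == pytest.approx([-1.0, 1.0])

    def test_round_trip_from_euclidean_points(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(_dm([str(i) for i in range(50)], d), k=2)
        coords = res.coordinates
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.abs(recon - d).max() < 1e-8

    def test_equidistant_triplet_gives_equal_eigenvalues(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        res = pcoa(_dm(list("abc"), d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_coordinates_are_centered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(_dm([str(i) for i in range(10)], d))
        assert np.abs(res.coordinates.mean(axis=0)).max() < 1e-10

    def test_matches_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ours = pcoa(_dm([str(i) for i in range(12)], d), k=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d, [str(i) for i in range(12)])
        )
        assert ours.eigenvalues == pytest.approx(
            theirs.eigvals.to_numpy()[:3], rel=1e-8
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            _dm(["a", "b"], [[0, 1], [2, 0]])


def _cluster_data(rng, n_per=4, shift=0.0):
    pts = np.vstack(
        [rng.normal(0, 1, size=(n_per, 2)), rng.normal(shift, 1, size=(n_per, 2))]
    )
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    ids = [str(i) for i in range(2 * n_per)]
    return _dm(ids, d), ["g1"] * n_per + ["g2"] * n_per


class TestPermanova:
    def test_separated_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(0)
        d, labels = _cluster_data(rng, n_per=6, shift=50.0)
        f, p = permanova(d, labels, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)
        assert f > 100

    def test_deterministic_given_seed_and_label_renaming_invariant(self):
        rng = np.random.default_rng(1)
        d, labels = _cluster_data(rng, shift=1.0)
        out1 = permanova(d, labels, n_perm=99, seed=7)
        out2 = permanova(d, labels, n_perm=99, seed=7)
        renamed = ["x" if g == "g1" else "y" for g in labels]
        out3 = permanova(d, renamed, n_perm=99, seed=7)
        assert out1 == out2 == out3

    def test_pseudo_f_matches_brute_force(self):
        """Exhaustive check of the sum-of-squares partition for N <= 8."""
        rng = np.random.default_rng(2)
        d, labels = _cluster_data(rng, n_per=4, shift=2.0)
        f_obs, _ = permanova(d, labels, n_perm=1, seed=0)
        # brute force from the definition
        n = d.n
        dmat = d.values
        groups = {g: [i for i, lab in enumerate(labels) if lab == g]
                  for g in set(labels)}
        ss_total = sum(
            dmat[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_within = sum(
            sum(dmat[i, j] ** 2 for i, j in itertools.combinations(idx, 2))
            / len(idx)
            for idx in groups.values()
        )
        a = len(groups)
        f_expect = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
        assert f_obs == pytest.approx(f_expect, rel=1e-10)

    def test_p_agrees_with_exhaustive_enumeration(self):
        """For N = 8 the permutation p converges to the exhaustive tail."""
        rng = np.random.default_rng(3)
        d, labels = _cluster_data(rng, n_per=4, shift=2.5)
        from lbqc.diversity import _permanova_f

        d2 = d.values**2
        code = np.array([0] * 4 + [1] * 4)
        f_obs = _permanova_f(d2, code, 2)
        fs = [
            _permanova_f(d2, np.array(perm), 2)
            for perm in set(itertools.permutations(code))
        ]
        exact = sum(f >= f_obs for f in fs) / len(fs)
        _, p_hat = permanova(d, labels, n_perm=4000, seed=0)
        assert p_hat == pytest.approx(exact, abs=0.02)

    def test_single_group_rejected(self):
        d = _dm(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            permanova(d, ["g", "g"])

    def test_matches_scikit_bio_pseudo_f(self):
        import skbio

        rng = np.random.default_rng(4)
        d, labels = _cluster_data(rng, n_per=5, shift=1.5)
        f_obs, _ = permanova(d, labels, n_perm=1, seed=0)
        res = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, list(d.sample_ids)),
            grouping=labels,
            permutations=9,
        )
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-8)


class TestCompleteLinkage:
    def test_hand_traced_merges(self):
        d = _dm(["A", "B", "C"], [[0, 1, 4], [1, 0, 5], [4, 5, 0]])
        dend = complete_linkage(d)
        assert dend.merge_heights.tolist() == pytest.approx([1.0, 5.0])

    def test_cut_below_first_merge_gives_singletons(self):
        d = _dm(["A", "B", "C"], [[0, 1, 4], [1, 0, 5], [4, 5, 0]])
        labels = cut(complete_linkage(d), 0.5)
        assert len(set(labels.values())) == 3

    def test_cut_at_top_gives_one_cluster(self):
        d = _dm(["A", "B", "C"], [[0, 1, 4], [1, 0, 5], [4, 5, 0]])
        labels = cut(complete_linkage(d), 5.0)
        assert len(set(labels.values())) == 1

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        pts = rng.random((15, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dend = complete_linkage(_dm([str(i) for i in range(15)], d))
        heights = dend.merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_distance_matrix_from_proportions(self):
        p = ProportionTable(
            pd.DataFrame(
                {"s1": [1.0, 0.0], "s2": [0.0, 1.0], "s3": [0.5, 0.5]},
                index=["o1", "o2"],
            )
        )
        d = distance_matrix(p)
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 2] == pytest.approx(0.5)
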