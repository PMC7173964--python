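import math

import numpy as np
import pandas as pd
import pytest

from hemimorph import (
    DotProps,
    ExponentialScore,
    SimilarityMatrix,
    TabulatedScore,
    all_to_all,
    consolidate_groups,
    filter_non_sibling,
    hemilineage_heatmap,
    mean_normalized_score,
    raw_score,
    select_pairs,
    to_dotprops,
)

from conftest import make_path, random_tree
from oracles import union_find_components


def random_cloud(rng, n):
    points = rng.uniform(0, 50, size=(n, 3))
    tangents = rng.normal(size=(n, 3))
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return DotProps(points=points, tangents=tangents, k_neighbors=5, spacing=1.0)


class TestDotprops:
    def test_straight_line_resampling_and_tangents(self):
        skel = make_path([0.0, 100.0])
        dp = to_dotprops(skel, spacing=1.0, k=5)
        assert len(dp) == 101
        axis = np.array([1.0, 0, 0])
        assert np.all(np.abs(dp.tangents @ axis) > 1 - 1e-9)

    def test_elbow_tangents_align_with_arms(self):
        # right angle: along x to 50, then along y to 50
        skel = make_path([0, 50, 50], [0, 0, 50])
        dp = to_dotprops(skel, spacing=1.0, k=5)
        x_axis, y_axis = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        far_x = dp.points[:, 0] < 40
        far_y = dp.points[:, 1] > 10
        assert np.all(np.abs(dp.tangents[far_x] @ x_axis) > 0.99)
        assert np.all(np.abs(dp.tangents[far_y & (dp.points[:, 1] > 15)] @ y_axis) > 0.99)

    def test_rotation_invariance_of_scores(self):
        rng = np.random.default_rng(0)
        a = to_dotprops(random_tree(rng, 30), spacing=2.0, k=5)
        b = to_dotprops(random_tree(rng, 30), spacing=2.0, k=5)
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )

        def rotate(dp):
            return DotProps(dp.points @ rot.T, dp.tangents @ rot.T, dp.k_neighbors, dp.spacing)

        before = mean_normalized_score(a, b)
        after = mean_normalized_score(rotate(a), rotate(b))
        assert after == pytest.approx(before, rel=1e-9)

    def test_too_few_points_suggests_smaller_k(self):
        skel = make_path([0.0, 2.0])
        with pytest.raises(ValueError, match="smaller k"):
            to_dotprops(skel, spacing=1.0, k=50)


class TestScoring:
    def test_self_raw_score_is_n_times_f01(self):
        rng = np.random.default_rng(1)
        dp = random_cloud(rng, 40)
        f = ExponentialScore(sigma=3.0)
        assert raw_score(dp, dp, f) == pytest.approx(40 * 1.0)

    def test_two_point_closed_form(self):
        t = np.array([[1.0, 0, 0]])
        a = DotProps(np.array([[0.0, 0, 0]]), t, 1, 1.0)
        b = DotProps(np.array([[3.0, 0, 0]]), t, 1, 1.0)
        assert raw_score(a, b, ExponentialScore(sigma=3.0)) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_nearest_neighbour(self, seed):
        rng = np.random.default_rng(seed)
        q, t = random_cloud(rng, 30), random_cloud(rng, 45)
        f = ExponentialScore(sigma=3.0)
        brute = 0.0
        for p, tan in zip(q.points, q.tangents):
            d = np.linalg.norm(t.points - p, axis=1)
            j = int(np.argmin(d))
            brute += f(d[j], abs(float(tan @ t.tangents[j])))
        assert raw_score(q, t, f) == pytest.approx(brute, rel=1e-12)

    def test_tabulated_score_monotone_bins(self):
        f = TabulatedScore([0, 2, 5, 20], [0, 0.5, 1.0], [[1, 2], [0.5, 1], [0.1, 0.2]])
        assert f(np.array([1.0]), np.array([0.9]))[0] == 2
        assert f(np.array([10.0]), np.array([0.1]))[0] == 0.1
        assert f(np.array([100.0]), np.array([2.0]))[0] == 0.2  # clipped

    def test_normalized_identical_clouds_score_one(self):
        rng = np.random.default_rng(2)
        dp = random_cloud(rng, 25)
        assert mean_normalized_score(dp, dp) == pytest.approx(1.0)

    def test_normalized_score_vanishes_at_distance(self):
        t = np.tile([1.0, 0, 0], (5, 1))
        a = DotProps(np.arange(15.0).reshape(5, 3), t, 1, 1.0)
        b = DotProps(np.arange(15.0).reshape(5, 3) + 100.0, t, 1, 1.0)
        assert 0 < mean_normalized_score(a, b) < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_exact(self, seed):
        rng = np.random.default_rng(10 + seed)
        a, b = random_cloud(rng, 20), random_cloud(rng, 30)
        assert mean_normalized_score(a, b) == mean_normalized_score(b, a)


class TestMatrix:
    def test_identical_neurons_score_one_off_diagonal(self):
        rng = np.random.default_rng(3)
        dp = random_cloud(rng, 20)
        m = all_to_all([("x", dp), ("y", dp)])
        assert m.score("x", "y") == pytest.approx(1.0)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_duplicate_labels_rejected(self):
        rng = np.random.default_rng(4)
        dp = random_cloud(rng, 10)
        with pytest.raises(ValueError, match="duplicate"):
            all_to_all([("x", dp), ("x", dp)])

    def test_matrix_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(5)
        clouds = [(f"n{i}", random_cloud(rng, 15)) for i in range(4)]
        m = all_to_all(clouds)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = mean_normalized_score(clouds[i][1], clouds[j][1])
                assert m.score(f"n{i}", f"n{j}") == pytest.approx(expected)

    def test_csv_round_trip_and_autodetection(self, tmp_path):
        rng = np.random.default_rng(6)
        clouds = [(f"CREa1A_P{i:02d}", random_cloud(rng, 12)) for i in range(1, 4)]
        m = all_to_all(clouds)
        p = tmp_path / "m.csv"
        m.to_csv(p)
        back = SimilarityMatrix.read_csv(p)
        assert back.normalized and back.symmetrized
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)

    def test_asymmetric_matrix_symmetrized_by_averaging(self):
        frame = pd.DataFrame(
            [[1.0, 0.4], [0.2, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        m = SimilarityMatrix(frame, normalized=True, symmetrized=False)
        assert m.symmetrize().score("a", "b") == pytest.approx(0.3)


class TestPairsAndGroups:
    def test_all_zero_matrix_yields_no_pairs(self):
        frame = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        m = SimilarityMatrix(frame, True, True)
        assert select_pairs(m, 0.3) == []

    def test_cutoff_is_strict(self):
        frame = pd.DataFrame(
            [[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        assert select_pairs(SimilarityMatrix(frame, True, True), 0.3) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_pairs_match_exhaustive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(10, 10))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        labels = [f"n{i}" for i in range(10)]
        m = SimilarityMatrix(pd.DataFrame(vals, index=labels, columns=labels), True, True)
        got = set(select_pairs(m, 0.5))
        expected = {
            (labels[i], labels[j])
            for i in range(10)
            for j in range(10)
            if i < j and vals[i, j] > 0.5
        }
        assert got == expected

    def test_sibling_filter_definition(self):
        pairs = [("CREa1A_P01", "CREa1A_P02"), ("CREa1A_P01", "CREa2A_P01")]
        kept = filter_non_sibling(pairs)
        assert kept == [("CREa1A_P01", "CREa2A_P01")]
        assert filter_non_sibling(kept) == kept  # idempotent

    def test_sibling_filter_names_unparseable_label(self):
        with pytest.raises(ValueError, match="garbage"):
            filter_non_sibling([("CREa1A_P01", "garbage")])

    def test_consolidation_example(self):
        groups = consolidate_groups([("a", "b"), ("b", "c"), ("d", "e")])
        assert [sorted(g.members) for g in groups] == [["a", "b", "c"], ["d", "e"]]
        assert [g.id for g in groups] == [1, 2]

    @pytest.mark.parametrize("seed", range(6))
    def test_consolidation_matches_union_find(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"n{i}" for i in range(25)]
        pairs = [
            tuple(sorted(rng.choice(labels, size=2, replace=False)))
            for _ in range(30)
        ]
        got = [g.members for g in consolidate_groups(pairs)]
        assert got == union_find_components(pairs)


class TestHemilineageHeatmap:
    def _matrix(self):
        labels = [f"CREa1A_P{i:02d}" for i in range(1, 5)] + ["CREa2A_P01"]
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, size=(5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        return SimilarityMatrix(pd.DataFrame(vals, index=labels, columns=labels), True, True)

    def test_native_order_returns_identical_submatrix(self):
        m = self._matrix()
        order = [f"CREa1A_P{i:02d}" for i in range(1, 5)]
        hm = hemilineage_heatmap(m, "CREa1A", order)
        np.testing.assert_allclose(hm.to_numpy(), m.frame.loc[order, order].to_numpy())

    def test_reversed_order_flips_pattern(self):
        m = self._matrix()
        order = [f"CREa1A_P{i:02d}" for i in range(1, 5)]
        fwd = hemilineage_heatmap(m, "CREa1A", order).to_numpy()
        rev = hemilineage_heatmap(m, "CREa1A", order[::-1]).to_numpy()
        np.testing.assert_allclose(rev, fwd[::-1, ::-1])

    def test_unknown_or_foreign_label_rejected(self):
        m = self._matrix()
        with pytest.raises(KeyError):
            hemilineage_heatmap(m, "CREa1A", ["CREa1A_P99"])
        with pytest.raises(ValueError, match="CREa2A_P01"):
            hemilineage_heatmap(m, "CREa1A", ["CREa2A_P01"])
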