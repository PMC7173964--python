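import numpy as np
import pytest

from hemimorph import (
    NeuronSkeleton,
    SkeletonNode,
    coefficient_of_variation,
    decompose_segments,
    locate_root_by_intensity,
    main_trajectory_length,
    prune_terminal_branches,
    read_swc,
    total_cable_length,
    write_swc,
)
from hemimorph.skeleton import SkeletonStructureError, SwcParseError

from conftest import attach_branch, make_path, random_tree
from oracles import brute_force_prune


class TestSwcIO:
    def test_three_node_path(self, tmp_path):
        p = tmp_path / "path.swc"
        p.write_text("# comment\n1 0 0 0 0 1 -1\n2 0 1 0 0 1 1\n3 0 2 0 0 1 2\n")
        skel = read_swc(p)
        assert len(skel) == 3
        assert len(list(skel.edges())) == 2
        assert total_cable_length(skel) == pytest.approx(2.0)

    def test_missing_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 0 0 0 0 1 -1\n5 0 1 0 0 1 99\n")
        with pytest.raises(SkeletonStructureError, match="99"):
            read_swc(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 0 0 0 0 1 -1\n2 0 oops 0 0 1 1\n")
        with pytest.raises(SwcParseError, match=":2"):
            read_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "tworoots.swc"
        p.write_text("1 0 0 0 0 1 -1\n2 0 1 0 0 1 -1\n")
        with pytest.raises(SkeletonStructureError, match="root"):
            read_swc(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_lossless(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, int(rng.integers(5, 60)), with_intensity=True)
        path = tmp_path / "t.swc"
        write_swc(skel, path)
        back = read_swc(path)
        assert len(back) == len(skel)
        for a, b in zip(skel.nodes, back.nodes):
            assert a.id == b.id and a.parent_id == b.parent_id
            np.testing.assert_allclose(a.position, b.position, rtol=1e-5)
            assert a.radius == pytest.approx(b.radius, rel=1e-5)
            assert a.intensity == pytest.approx(b.intensity, rel=1e-5)


class TestRooting:
    def test_root_at_max_intensity(self):
        skel = make_path([0, 1, 2, 3, 4], intensities=[1, 2, 9, 2, 1])
        root = locate_root_by_intensity(skel)
        assert root == 3  # middle node
        assert skel.root_id == 3
        assert len(skel.leaves()) == 2  # re-rooted path has two leaves

    def test_intensity_tie_breaks_to_lowest_id(self):
        skel = make_path([0, 1, 2], intensities=[5, 9, 9])
        assert locate_root_by_intensity(skel) == 2

    def test_missing_intensity_raises(self):
        skel = make_path([0, 1, 2])
        with pytest.raises(ValueError, match="explicit root"):
            locate_root_by_intensity(skel)

    @pytest.mark.parametrize("seed", range(5))
    def test_rerooting_preserves_edge_set_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, 40, with_intensity=True)
        edges_before = {frozenset(e) for e in skel.edges()}
        length_before = total_cable_length(skel)
        locate_root_by_intensity(skel)
        assert {frozenset(e) for e in skel.edges()} == edges_before
        assert total_cable_length(skel) == pytest.approx(length_before)


class TestSegments:
    def test_unbranched_path_is_single_trunk_segment(self):
        skel = make_path([0, 50, 100])
        segs = decompose_segments(skel)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(100)

    def test_y_tree_segments(self):
        # trunk 50, arms 30 and 60
        skel = make_path([0, 50])
        skel = attach_branch(skel, 2, [(0, 30, 0)], start_id=10)
        skel = attach_branch(skel, 2, [(0, -60, 0)], start_id=20)
        segs = decompose_segments(skel)
        by_kind = sorted((s.kind, round(s.length)) for s in segs)
        assert by_kind == [("internal", 50), ("terminal", 30), ("terminal", 60)]

    def test_single_node_yields_no_segments(self):
        skel = NeuronSkeleton([SkeletonNode(id=1, parent_id=None, position=np.zeros(3))])
        assert decompose_segments(skel) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_cable_length_conservation(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, int(rng.integers(5, 80)))
        segs = decompose_segments(skel)
        assert sum(s.length for s in segs) == pytest.approx(total_cable_length(skel))


def toy_trunk_with_side_branches():
    """Trunk 0->100 um with a 30-um branch at x=50 and a 60-um branch at x=80."""
    skel = make_path([0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
    skel = attach_branch(skel, 6, [(0, 15, 0), (0, 15, 0)], start_id=20)  # 30 um
    skel = attach_branch(skel, 9, [(0, 30, 0), (0, 30, 0)], start_id=30)  # 60 um
    return skel


class TestPruning:
    def test_zero_threshold_is_identity(self):
        skel = toy_trunk_with_side_branches()
        assert total_cable_length(prune_terminal_branches(skel, 0)) == pytest.approx(
            total_cable_length(skel)
        )

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prune_terminal_branches(make_path([0, 1]), -1)

    def test_unbranched_skeleton_never_pruned(self):
        skel = make_path([0, 5, 10])
        assert total_cable_length(prune_terminal_branches(skel, 1000)) == pytest.approx(10)

    def test_hand_traced_serial_fixpoint(self):
        """25 um removes the 20-um distal tail (merging the 60-um branch into a
        90-um terminal); 50 um then removes the 30-um branch; 140 um remains."""
        skel = toy_trunk_with_side_branches()
        assert total_cable_length(skel) == pytest.approx(190)
        after25 = prune_terminal_branches(skel, 25)
        assert total_cable_length(after25) == pytest.approx(170)
        after50 = prune_terminal_branches(after25, 50)
        assert total_cable_length(after50) == pytest.approx(140)
        assert main_trajectory_length(skel) == pytest.approx(140)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_removal(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, int(rng.integers(5, 50)))
        for threshold in (5.0, 12.0, 30.0):
            pruned = prune_terminal_branches(skel, threshold)
            assert {n.id for n in pruned.nodes} == brute_force_prune(skel, threshold)

    @pytest.mark.parametrize("seed", range(6))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(100 + seed)
        skel = random_tree(rng, 40)
        once = prune_terminal_branches(skel, 15.0)
        twice = prune_terminal_branches(once, 15.0)
        assert {n.id for n in once.nodes} == {n.id for n in twice.nodes}

    @pytest.mark.parametrize("seed", range(6))
    def test_remaining_cable_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(200 + seed)
        skel = random_tree(rng, 60)
        lengths = [
            total_cable_length(prune_terminal_branches(skel, t))
            for t in (0, 5, 10, 25, 50)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(lengths, lengths[1:]))

    def test_serial_equals_direct_when_no_short_merges(self):
        """With all internal segments >= 50 um, pruning at [10, 25, 50] serially
        equals direct fixpoint pruning at 50 (no merge builds a long branch
        from short parts)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            # comb: long trunk with short terminal teeth
            skel = make_path([0, 60, 120, 180, 240, 300])
            nid = 50
            for at in (2, 3, 4, 5):
                tooth = float(rng.uniform(3, 45))
                skel = attach_branch(skel, at, [(0, tooth, 0)], start_id=nid)
                nid += 10
            serial = skel
            for t in (10, 25, 50):
                serial = prune_terminal_branches(serial, t)
            direct = prune_terminal_branches(skel, 50)
            assert {n.id for n in serial.nodes} == {n.id for n in direct.nodes}


class TestLengthsAndCV:
    def test_unbranched_path_length_unchanged(self):
        assert main_trajectory_length(make_path([0, 100, 200])) == pytest.approx(200)

    @pytest.mark.parametrize("seed", range(5))
    def test_main_trajectory_bounded_by_total_cable(self, seed):
        rng = np.random.default_rng(300 + seed)
        skel = random_tree(rng, 50)
        assert main_trajectory_length(skel) <= total_cable_length(skel) + 1e-9

    def test_cv_values(self):
        assert coefficient_of_variation([100, 100, 100]) == 0.0
        assert coefficient_of_variation([10, 20, 30]) == pytest.approx(0.5)

    def test_cv_scale_invariance(self):
        vals = [12.0, 19.0, 31.0, 44.0]
        assert coefficient_of_variation(vals) == pytest.approx(
            coefficient_of_variation([v * 7.3 for v in vals])
        )

    def test_cv_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([5.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0, -3.0])
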